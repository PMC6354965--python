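"""Ten feature-selection algorithms behind one dispatch contract.

Five algorithms use only the omics view (t-test, Lasso, Cox, RegCox, MSS);
five additionally require the regulatory network (NetLasso, addDA2,
NetRank, stSVM, Survnet).  All return an ordered :class:`FeatureSet` of at
most ``k`` features (default 20).
"""

from __future__ import annotations

import pandas as pd

from ..network import Network
from ..simulate import SurvivalData
from ._base import FeatureSet, rank_order, top_k
from .diffusion import (NetRankConfig, RWKernelConfig, netrank, netrank_select,
                        netrank_solve, rw_kernel, stsvm_rank)
from .sampling import mss_rank
from .sparse import (NetLassoConfig, lasso_select, netlasso_fit,
                     netlasso_select, regcox_select)
from .subnetwork import (SubnetworkSearchConfig, addda2_select,
                         greedy_subnetwork_search, mutual_information,
                         survnet_select)
from .univariate import cox_rank, cox_univariate, ttest_rank, welch_t

ALGORITHMS = (
    "t-test", "Lasso", "NetLasso", "addDA2", "NetRank",
    "stSVM", "Cox", "RegCox", "MSS", "Survnet",
)
NETWORK_ALGORITHMS = ("NetLasso", "addDA2", "NetRank", "stSVM", "Survnet")
SURVIVAL_ALGORITHMS = ("Cox", "RegCox", "Survnet")

__all__ = [
    "ALGORITHMS", "NETWORK_ALGORITHMS", "SURVIVAL_ALGORITHMS",
    "FeatureSet", "rank_order", "top_k", "select",
    "ttest_rank", "welch_t", "cox_univariate", "cox_rank",
    "lasso_select", "netlasso_fit", "netlasso_select", "regcox_select",
    "NetLassoConfig", "NetRankConfig", "RWKernelConfig",
    "netrank", "netrank_solve", "netrank_select", "rw_kernel", "stsvm_rank",
    "SubnetworkSearchConfig", "mutual_information",
    "greedy_subnetwork_search", "addda2_select", "survnet_select",
    "mss_rank",
]


def select(
    algorithm: str,
    X: pd.DataFrame,
    outcome,
    net: Network | None = None,
    k: int = 20,
    seed: int = 0,
    level: str = "GE",
    survival: SurvivalData | None = None,
) -> FeatureSet:
    """Uniform dispatch: (algorithm, view, outcome, optional network, k).

    ``outcome`` is a binary label Series for label-driven algorithms or a
    :class:`SurvivalData` for survival-driven ones; pass ``survival``
    explicitly when ``outcome`` holds labels but the algorithm needs
    follow-up (Cox/RegCox/Survnet inside a classification benchmark).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if algorithm in NETWORK_ALGORITHMS and net is None:
        raise ValueError(f"{algorithm} requires a network")
    surv = survival if survival is not None else (
        outcome if isinstance(outcome, SurvivalData) else None
    )
    labels = outcome if not isinstance(outcome, SurvivalData) else None
    if algorithm in SURVIVAL_ALGORITHMS and surv is None:
        raise ValueError(f"{algorithm} requires survival data")
    if algorithm == "t-test":
        return ttest_rank(X, labels, k)
    if algorithm == "Lasso":
        return lasso_select(X, labels, k)
    if algorithm == "NetLasso":
        return netlasso_select(X, labels, net, k, level=level)
    if algorithm == "addDA2":
        return addda2_select(net, X, labels,
                             SubnetworkSearchConfig(level=level), k)
    if algorithm == "NetRank":
        return netrank_select(X, labels if labels is not None else surv,
                              net, k=k, level=level)
    if algorithm == "stSVM":
        return stsvm_rank(X, labels, net, k=k, level=level)
    if algorithm == "Cox":
        return cox_rank(X, surv, k)
    if algorithm == "RegCox":
        return regcox_select(X, surv, k)
    if algorithm == "MSS":
        return mss_rank(X, labels, k=k, seed=seed)
    if algorithm == "Survnet":
        return survnet_select(
            net, X, surv, SubnetworkSearchConfig(score_kind="cox_pvalue",
                                                 level=level), k)
    raise AssertionError("unreachable")
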