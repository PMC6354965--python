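"""Network diffusion ranking: PageRank-style NetRank and random-walk-kernel
smoothed t statistics (stSVM-style ranking).

NetRank iterates r_j <- (1-d) s_j + d * sum_i A_ij r_i / deg_i, i.e. a
personalized PageRank over the (weighted) regulatory network; with the
personalization s identically 1 this is the literal published update.  The
p-step random-walk kernel is K = ((alpha-1) I + D^{-1/2} A D^{-1/2})^p,
positive semidefinite for alpha >= 2; multiplying gene-wise t statistics by
K shares evidence between network neighbors before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..network import Network, build_matrices
from ..simulate import SurvivalData
from ._base import FeatureSet, top_k
from .univariate import cox_univariate, welch_t

__all__ = ["NetRankConfig", "RWKernelConfig", "netrank", "netrank_solve",
           "rw_kernel", "stsvm_rank", "netrank_select"]


@dataclass
class NetRankConfig:
    d: float = 0.85
    tol: float = 1e-9
    max_iter: int = 10_000
    personalization: np.ndarray | None = None  # per-node, nonnegative

    def __post_init__(self) -> None:
        if not 0 <= self.d < 1:
            raise ValueError("damping d must lie in [0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class RWKernelConfig:
    alpha_k: float = 2.0
    p: int = 3

    def __post_init__(self) -> None:
        if self.alpha_k < 2:
            raise ValueError("alpha_k >= 2 is required for a PSD kernel")
        if int(self.p) != self.p or self.p < 0:
            raise ValueError("p must be a nonnegative integer")


def _transition(net: Network) -> tuple[list[str], np.ndarray]:
    """Row-stochastic transition matrix P = D^{-1} A (zero rows if isolated)."""
    mats = build_matrices(net)
    deg = mats.degree
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(deg[:, None] > 0, mats.adjacency / np.where(deg, deg, 1.0)[:, None], 0.0)
    return mats.nodes, p


def netrank(net: Network, cfg: NetRankConfig | None = None) -> pd.Series:
    """Fixed point of the damped rank update by power iteration."""
    cfg = cfg or NetRankConfig()
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    nodes, p = _transition(net)
    s = np.ones(len(nodes)) if cfg.personalization is None else np.asarray(
        cfg.personalization, dtype=float
    )
    if s.shape != (len(nodes),):
        raise ValueError("personalization length must equal node count")
    if (s < 0).any():
        raise ValueError("personalization must be nonnegative")
    r = s.copy()
    for _ in range(cfg.max_iter):
        r_new = (1 - cfg.d) * s + cfg.d * (p.T @ r)
        if np.max(np.abs(r_new - r)) < cfg.tol:
            return pd.Series(r_new, index=nodes, name="netrank")
        r = r_new
    raise RuntimeError(f"netrank did not converge in {cfg.max_iter} iterations")


def netrank_solve(net: Network, cfg: NetRankConfig | None = None) -> pd.Series:
    """Direct linear solve of (I - d P^T) r = (1-d) s (oracle counterpart)."""
    cfg = cfg or NetRankConfig()
    nodes, p = _transition(net)
    s = np.ones(len(nodes)) if cfg.personalization is None else np.asarray(
        cfg.personalization, dtype=float
    )
    r = np.linalg.solve(np.eye(len(nodes)) - cfg.d * p.T, (1 - cfg.d) * s)
    return pd.Series(r, index=nodes, name="netrank")


def rw_kernel(net: Network, cfg: RWKernelConfig | None = None) -> pd.DataFrame:
    """p-step random-walk kernel ((alpha-1) I + D^{-1/2} A D^{-1/2})^p."""
    cfg = cfg or RWKernelConfig()
    mats = build_matrices(net)
    base = (cfg.alpha_k - 1.0) * np.eye(len(mats.nodes)) + mats.normalized_adjacency
    k = np.linalg.matrix_power(base, int(cfg.p))
    return pd.DataFrame(k, index=mats.nodes, columns=mats.nodes)


def _node_stats_from_labels(
    X: pd.DataFrame, y: pd.Series, net: Network, level: str
) -> tuple[pd.Series, dict[str, str]]:
    """Per-node Welch t over mapped features (0 for unmeasured nodes)."""
    t = pd.Series(welch_t(X.values, y.loc[X.index].values), index=X.columns)
    node_feat = {
        n: f for n, f in net.features_for_level(level).items() if f in X.columns
    }
    node_t = pd.Series(
        {n: float(t[f]) for n, f in node_feat.items()}
    ).reindex(net.nodes, fill_value=0.0)
    return node_t, node_feat


def stsvm_rank(
    X: pd.DataFrame,
    y: pd.Series,
    net: Network,
    cfg: RWKernelConfig | None = None,
    k: int = 20,
    level: str = "GE",
) -> FeatureSet:
    """Rank by network-smoothed |t|: t_tilde = t^T K over mapped features.

    Features not mapped to any network node keep their raw |t| (the network
    typically covers only part of a level's feature space).
    """
    cfg = cfg or RWKernelConfig()
    node_t, node_feat = _node_stats_from_labels(X, y, net, level)
    kern = rw_kernel(net, cfg)
    smoothed = pd.Series(node_t.values @ kern.values, index=kern.index)
    t_raw = pd.Series(welch_t(X.values, y.loc[X.index].values), index=X.columns)
    scores = t_raw.abs()
    for node, feat in node_feat.items():
        scores[feat] = abs(float(smoothed[node]))
    return top_k(list(X.columns), scores.values, k, "stSVM")


def netrank_select(
    X: pd.DataFrame,
    outcome: pd.Series | SurvivalData,
    net: Network,
    cfg: NetRankConfig | None = None,
    k: int = 20,
    level: str = "GE",
) -> FeatureSet:
    """NetRank feature selection.

    The personalization vector is outcome-driven - per-node |Welch t| for
    class labels or |Cox z| for survival, normalized to mean 1 - because the
    bare damped update is outcome-independent and cannot rank prognostic
    relevance.  Pass a config with ``personalization`` set to override
    (``numpy.ones`` reproduces the literal published update).
    """
    cfg = cfg or NetRankConfig()
    node_feat = {
        n: f for n, f in net.features_for_level(level).items() if f in X.columns
    }
    if cfg.personalization is None:
        if isinstance(outcome, SurvivalData):
            sub = outcome.loc(X.index)
            stat = pd.Series(
                {n: abs(cox_univariate(X[f], sub)[1]) for n, f in node_feat.items()}
            ).reindex(net.nodes, fill_value=0.0)
        else:
            stat, _ = _node_stats_from_labels(X, outcome, net, level)
            stat = stat.abs()
        mean = stat.mean()
        s = (stat / mean).values if mean > 0 else np.ones(net.n_nodes)
        cfg = NetRankConfig(cfg.d, cfg.tol, cfg.max_iter, personalization=s)
    ranks = netrank(net, cfg)
    best: dict[str, float] = {}
    for node, feat in node_feat.items():  # several nodes may share a feature
        best[feat] = max(best.get(feat, -np.inf), float(ranks[node]))
    ids = list(best)
    return top_k(ids, np.asarray([best[f] for f in ids]), k, "NetRank")
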