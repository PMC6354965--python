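"""Greedy subnetwork biomarker search.

Subnetworks are grown greedily from every node: at each step the neighbor
whose addition most improves the metagene score joins, until the relative
gain drops below ``min_improvement`` or ``max_size`` is reached.  The
metagene of a candidate subnetwork is the row-wise sum of its members'
(z-scored) feature values - the "addition" aggregation.  Two scoring
functions are supported: mutual information between the mean-binarized
metagene and the class labels (addDA2-style), and -log10 of the univariate
Cox PH p-value of the metagene against survival (Survnet-style).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from ..network import Network
from ..simulate import SurvivalData
from ._base import FeatureSet, top_k
from .univariate import _breslow_parts, cox_univariate

__all__ = [
    "SubnetworkSearchConfig",
    "mutual_information",
    "greedy_subnetwork_search",
    "addda2_select",
    "survnet_select",
]


@dataclass
class SubnetworkSearchConfig:
    max_size: int = 10
    min_improvement: float = 0.05  # relative score gain to accept a growth step
    score_kind: str = "mutual_information"  # or "cox_pvalue"
    level: str = "GE"

    def __post_init__(self) -> None:
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        if self.min_improvement < 0:
            raise ValueError("min_improvement must be >= 0")
        if self.score_kind not in ("mutual_information", "cox_pvalue"):
            raise ValueError(f"unknown score_kind {self.score_kind!r}")


def mutual_information(a: Sequence, b: Sequence) -> float:
    """Mutual information in bits from the empirical joint distribution."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    n = len(a)
    if n == 0:
        raise ValueError("empty vectors")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log2(joint[mask] / (pa @ pb)[mask])))


class _Scorer:
    """Metagene scorer over a fixed node->column mapping."""

    def __init__(self, X: pd.DataFrame, outcome, cfg: SubnetworkSearchConfig,
                 net: Network):
        node_feat = {
            n: f for n, f in net.features_for_level(cfg.level).items()
            if f in X.columns
        }
        self.nodes = list(node_feat)
        self.cols = {n: X.columns.get_loc(f) for n, f in node_feat.items()}
        self.feat = node_feat
        self.x = X.values
        self.cfg = cfg
        if cfg.score_kind == "mutual_information":
            if isinstance(outcome, SurvivalData):
                raise TypeError("mutual_information scoring needs class labels")
            self.y = np.asarray(outcome.loc[X.index].values)
            self.surv = None
        else:
            if not isinstance(outcome, SurvivalData):
                raise TypeError("cox_pvalue scoring needs SurvivalData")
            self.surv = outcome.loc(X.index)
            self.y = None
            # Breslow risk-set structure is fixed across candidate metagenes;
            # precompute it once so each greedy step is a lean Newton solve
            dummy = np.zeros(len(X))
            _, self._es, self._riskend = _breslow_parts(
                dummy,
                self.surv.time.values.astype(float),
                self.surv.event.values.astype(int),
            )
            self._order = np.argsort(-self.surv.time.values, kind="stable")

    def metagene(self, nodes: Sequence[str]) -> np.ndarray:
        return self.x[:, [self.cols[n] for n in nodes]].sum(axis=1)

    def _neglog10_cox_p_many(self, m: np.ndarray) -> np.ndarray:
        """-log10 Wald p of univariate Cox fits, one per column of ``m``.

        Vectorized Newton over all candidate metagenes at once; the Breslow
        risk-set structure is shared, so each iteration is a handful of
        cumulative sums on an (n_samples x n_candidates) block.
        """
        xs = m[self._order, :]
        sd = xs.std(axis=0)
        ok = sd > 0
        xs = (xs - xs.mean(axis=0)) / np.where(ok, sd, 1.0)
        es, riskend = self._es, self._riskend
        beta = np.zeros(m.shape[1])
        info = np.ones(m.shape[1])
        for _ in range(25):
            eta = np.clip(xs * beta, -500, 500)
            w = np.exp(eta)
            cw = np.cumsum(w, axis=0)[riskend]
            mean = np.cumsum(w * xs, axis=0)[riskend] / cw
            u = (xs[es] - mean[es]).sum(axis=0)
            info = (np.cumsum(w * xs * xs, axis=0)[riskend][es] / cw[es]
                    - mean[es] ** 2).sum(axis=0)
            pos = info > 0
            step = np.clip(np.where(pos, u / np.where(pos, info, 1.0), 0.0),
                           -2.0, 2.0)
            beta += step
            if np.max(np.abs(step)) < 1e-8:
                break
        z = np.abs(beta) * np.sqrt(np.maximum(info, 0.0))
        logp = np.log(2.0) + special.log_ndtr(-z)
        out = -logp / np.log(10.0)
        return np.where(ok & (info > 0), out, 0.0)

    def score_many(self, base: Sequence[str], additions: Sequence[str]) -> np.ndarray:
        """Scores of base+[a] for each candidate addition a (one batch)."""
        base_m = self.metagene(base) if base else 0.0
        cols = [self.cols[a] for a in additions]
        m = self.x[:, cols] + (base_m[:, None] if len(base) else 0.0)
        if self.cfg.score_kind == "cox_pvalue":
            return self._neglog10_cox_p_many(m)
        return np.array([
            mutual_information(m[:, j] > m[:, j].mean(), self.y)
            for j in range(m.shape[1])
        ])

    def score(self, nodes: Sequence[str]) -> float:
        nodes = list(nodes)
        return float(self.score_many(nodes[:-1], [nodes[-1]])[0])


def greedy_subnetwork_search(
    net: Network,
    X: pd.DataFrame,
    outcome,
    cfg: SubnetworkSearchConfig | None = None,
) -> list[tuple[tuple[str, ...], float]]:
    """Greedy metagene search seeded at every measured node.

    Returns deduplicated subnetworks as (sorted node tuple, score), ordered
    by score descending (ties: lexicographic node tuple).
    """
    cfg = cfg or SubnetworkSearchConfig()
    scorer = _Scorer(X, outcome, cfg, net)
    single_scores = scorer.score_many([], scorer.nodes)
    singles = dict(zip(scorer.nodes, (float(s) for s in single_scores)))
    seeds = sorted(scorer.nodes, key=lambda n: (-singles[n], n))
    found: dict[tuple[str, ...], float] = {}
    for seed in seeds:
        members = [seed]
        score = singles[seed]
        while len(members) < cfg.max_size:
            frontier = set()
            for m in members:
                frontier |= set(net.graph.neighbors(m))
            frontier = sorted(
                (n for n in frontier if n in scorer.cols and n not in members)
            )
            if not frontier:
                break
            cand_scores = scorer.score_many(members, frontier)
            j = int(np.lexsort((frontier, -np.asarray(cand_scores)))[0])
            best_score = float(cand_scores[j])
            gain = (best_score - score) / max(abs(score), 1e-12)
            if not gain >= cfg.min_improvement or best_score <= score:
                break
            members.append(frontier[j])
            score = best_score
        key = tuple(sorted(members))
        if key not in found or found[key] < score:
            found[key] = score
    return sorted(found.items(), key=lambda kv: (-kv[1], kv[0]))


def _emit_members(
    subnets: list[tuple[tuple[str, ...], float]],
    scorer: _Scorer,
    k: int,
    algorithm: str,
) -> FeatureSet:
    """Member features of top subnetworks until k collected.

    Each feature's score is the best score among subnetworks containing it,
    so emitted features honor the non-increasing-score convention.
    """
    best: dict[str, float] = {}
    ordered: list[str] = []
    for nodes, score in subnets:
        for n in nodes:
            f = scorer.feat[n]
            if f not in best:
                best[f] = score
                ordered.append(f)
        if len(ordered) >= k:
            break
    ordered = ordered[:k]
    return top_k(ordered, np.asarray([best[f] for f in ordered]), k, algorithm)


def addda2_select(
    net: Network,
    X: pd.DataFrame,
    y: pd.Series,
    cfg: SubnetworkSearchConfig | None = None,
    k: int = 20,
) -> FeatureSet:
    """Mutual-information-scored subnetwork search; emits member features."""
    cfg = cfg or SubnetworkSearchConfig(score_kind="mutual_information")
    subnets = greedy_subnetwork_search(net, X, y, cfg)
    return _emit_members(subnets, _Scorer(X, y, cfg, net), k, "addDA2")


def survnet_select(
    net: Network,
    X: pd.DataFrame,
    surv: SurvivalData,
    cfg: SubnetworkSearchConfig | None = None,
    k: int = 20,
) -> FeatureSet:
    """Cox-p-scored subnetwork search; emits member features."""
    cfg = cfg or SubnetworkSearchConfig(score_kind="cox_pvalue")
    if cfg.score_kind != "cox_pvalue":
        raise ValueError("survnet requires score_kind='cox_pvalue'")
    subnets = greedy_subnetwork_search(net, X, surv, cfg)
    return _emit_members(subnets, _Scorer(X, surv, cfg, net), k, "Survnet")
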