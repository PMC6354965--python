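"""Signature-based survival stratification.

Single-omics signatures (per-level FeatureSets) are column-concatenated
into a z-scored signature matrix; samples are clustered (k-means, spectral
or Ward hierarchical) into k groups; Kaplan-Meier curves are estimated per
group and a k-group log-rank test quantifies the separation.  Kaplan-Meier
estimation and the log-rank statistic are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.spatial.distance import pdist
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering

from .selection import FeatureSet
from .simulate import MultiOmicsDataset, SurvivalData, zscore

__all__ = [
    "SignatureMatrix", "StratificationResult", "combine_signatures",
    "cluster_samples", "km_estimate", "logrank_test", "stratify",
]


@dataclass
class SignatureMatrix:
    """Samples x signature-feature matrix with level-tagged columns."""

    values: pd.DataFrame  # columns "LEVEL:feature"
    provenance: tuple[str, ...]


@dataclass
class StratificationResult:
    assignments: pd.Series
    method: str
    statistic: float
    df: int
    p_value: float
    km_curves: dict[int, pd.DataFrame]  # group -> (time, survival)


def combine_signatures(
    sets: Sequence[FeatureSet], data: MultiOmicsDataset
) -> SignatureMatrix:
    """Column-concatenate per-level signatures on the shared samples.

    Each FeatureSet must carry its level in ``context['level']``; duplicate
    (level, feature) columns are dropped; columns are z-scored.
    """
    frames = []
    seen: set[tuple[str, str]] = set()
    prov = []
    for fs in sets:
        level = fs.context.get("level")
        if level is None or level not in data.levels:
            raise ValueError("each FeatureSet needs context['level'] in the data")
        cols = [f for f in fs.features
                if (level, f) not in seen and f in data.levels[level].columns]
        seen.update((level, f) for f in cols)
        block = data.levels[level][cols]
        block.columns = [f"{level}:{c}" for c in cols]
        frames.append(block)
        prov.append(f"{fs.algorithm}@{level}")
    if not frames:
        raise ValueError("no signature features resolve to data columns")
    common = frames[0].index
    for fr in frames[1:]:
        common = common.intersection(fr.index)
    if len(common) == 0:
        raise ValueError("empty sample intersection across levels")
    joined = pd.concat([fr.loc[common] for fr in frames], axis=1)
    return SignatureMatrix(zscore(joined), tuple(prov))


def cluster_samples(
    sig: SignatureMatrix, method: str = "kmeans", k: int = 3, seed: int = 0
) -> pd.Series:
    """Cluster samples on the signature matrix.

    k-means: best of 20 restarts by inertia.  spectral: RBF affinity with
    median-heuristic bandwidth.  hierarchical: Ward linkage on Euclidean
    distances, cut at k.
    """
    x = sig.values.values
    if k > len(x):
        raise ValueError("more clusters than samples")
    if method == "kmeans":
        model = KMeans(n_clusters=k, n_init=20, random_state=seed)
        lab = model.fit_predict(x)
    elif method == "spectral":
        med = float(np.median(pdist(x)))
        gamma = 1.0 / (2.0 * med**2) if med > 0 else 1.0
        model = SpectralClustering(
            n_clusters=k, affinity="rbf", gamma=gamma, random_state=seed,
            assign_labels="kmeans", n_init=20,
        )
        lab = model.fit_predict(x)
    elif method == "hierarchical":
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        lab = model.fit_predict(x)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return pd.Series(lab, index=sig.values.index, name="cluster")


def km_estimate(surv: SurvivalData) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve as a (time, survival) step table."""
    if len(surv.time) == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time.values, surv.event.values)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.values, "survival": sf.iloc[:, 0].values}
    )


def km_at(curve: pd.DataFrame, t: float) -> float:
    """Evaluate a KM step table at time t (right-continuous)."""
    below = curve[curve["time"] <= t]
    return float(below["survival"].iloc[-1]) if len(below) else 1.0


def logrank_test(
    surv: SurvivalData, groups: pd.Series
) -> tuple[float, int, float]:
    """k-group log-rank test: (chi-square, df, p).

    Observed-minus-expected formulation with hypergeometric variance at
    tied event times (lifelines' multivariate log-rank).
    """
    g = groups.loc[surv.samples]
    sizes = g.value_counts()
    if (sizes > 0).sum() < 2:
        raise ValueError("need at least two nonempty groups")
    if surv.event.sum() == 0:
        raise ValueError("log-rank undefined with no observed events")
    res = multivariate_logrank_test(
        surv.time.values, g.values, surv.event.values
    )
    df = int(sizes.gt(0).sum() - 1)
    return float(res.test_statistic), df, float(res.p_value)


def stratify(
    sig: SignatureMatrix,
    surv: SurvivalData,
    method: str = "kmeans",
    k: int = 3,
    seed: int = 0,
) -> StratificationResult:
    """Cluster on the signature, then KM curves per group plus log-rank."""
    common = sig.values.index.intersection(surv.samples)
    sub_sig = SignatureMatrix(sig.values.loc[common], sig.provenance)
    sub_surv = surv.loc(common)
    assign = cluster_samples(sub_sig, method, k, seed)
    stat, df, p = logrank_test(sub_surv, assign)
    curves = {
        int(grp): km_estimate(sub_surv.loc(assign.index[assign == grp]))
        for grp in sorted(assign.unique())
    }
    return StratificationResult(assign, method, stat, df, p, curves)
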