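"""Cross-validation benchmark harness.

Repeated stratified k-fold cross-validation with a shared fold plan:
features are selected on each training split, a classifier (linear SVM or
random forest) is trained on the selected columns and scored on the held-
out fold, and AUC / AUPR / accuracy / confusion counts are recorded per
(algorithm x network x repeat x fold).  Per-fold selections are retained so
frequently-selected features (FSFs) can be aggregated afterwards.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_curve, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._seeds import int_seed
from .network import Network
from .selection import FeatureSet, NETWORK_ALGORITHMS, select
from .simulate import MultiOmicsDataset, PrognosisLabels, SurvivalData

__all__ = [
    "CVPlan", "SelectionHistory", "make_cv_plan", "run_benchmark",
    "evaluate_feature_sets", "auc", "aupr", "accuracy", "confusion",
    "odds_ratio", "paired_ttest", "fsf", "comparative_groups",
    "threshold_sensitivity",
]


@dataclass
class CVPlan:
    """Repeated stratified fold assignments, reusable across algorithms."""

    n_folds: int
    n_repeats: int
    samples: pd.Index
    folds: list[np.ndarray]  # per repeat: fold id per sample
    seed: int

    def iter_splits(self):
        """Yield (repeat, fold, train_samples, test_samples)."""
        for rep, assignment in enumerate(self.folds):
            for f in range(self.n_folds):
                test = self.samples[assignment == f]
                train = self.samples[assignment != f]
                yield rep, f, train, test


def make_cv_plan(
    labels: PrognosisLabels | pd.Series,
    n_folds: int = 10,
    n_repeats: int = 30,
    seed: int = 0,
) -> CVPlan:
    """Stratified fold plan over the labeled (non-excluded) samples."""
    y = labels.binary() if isinstance(labels, PrognosisLabels) else labels
    counts = y.value_counts()
    if (counts < n_folds).any():
        raise ValueError(
            f"smallest class has {counts.min()} samples; need >= {n_folds}"
        )
    folds = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=int_seed(seed, "cv", rep),
        )
        assignment = np.empty(len(y), dtype=int)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y.values)):
            assignment[test_idx] = f
        folds.append(assignment)
    return CVPlan(n_folds, n_repeats, y.index, folds, seed)


# ---------------------------------------------------------------- metrics

def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC = Mann-Whitney pairwise statistic with 0.5 credit for ties."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for a single-class fold")
    return float(roc_auc_score(labels, scores))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the PR curve with monotone precision interpolation."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPR undefined for a single-class fold")
    prec, rec, _ = precision_recall_curve(labels, scores)
    order = np.argsort(-rec, kind="stable")
    r, p = rec[order], prec[order]
    env = np.maximum.accumulate(p)  # best precision achievable at recall >= r
    area = 0.0
    j = 0
    while j < len(r):
        k = j
        while k + 1 < len(r) and r[k + 1] == r[j]:
            k += 1
        nxt = r[k + 1] if k + 1 < len(r) else 0.0
        area += (r[j] - nxt) * env[k]
        j = k + 1
    return float(area)


def accuracy(scores: Sequence[float], labels: Sequence[int],
             cutoff: float = 0.5) -> float:
    pred = (np.asarray(scores) > cutoff).astype(int)
    return float(np.mean(pred == np.asarray(labels)))


def confusion(scores, labels, cutoff: float = 0.5) -> dict[str, int]:
    pred = (np.asarray(scores) > cutoff).astype(int)
    labels = np.asarray(labels)
    return {
        "tp": int(np.sum((pred == 1) & (labels == 1))),
        "fp": int(np.sum((pred == 1) & (labels == 0))),
        "tn": int(np.sum((pred == 0) & (labels == 0))),
        "fn": int(np.sum((pred == 0) & (labels == 1))),
    }


def odds_ratio(tp: float, fp: float, tn: float, fn: float) -> float:
    """(TP*TN)/(FP*FN), Haldane-Anscombe 0.5 correction when any cell is 0."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if min(tp, fp, tn, fn) == 0:
        tp, fp, tn, fn = tp + 0.5, fp + 0.5, tn + 0.5, fn + 0.5
    return float((tp * tn) / (fp * fn))


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value (p=1 when all differences vanish)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.allclose(d.std(), 0):
        return 1.0 if np.allclose(d, 0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


# ------------------------------------------------------------- classifiers

def _fit_score(x_tr, y_tr, x_te, classifier: str, seed: int) -> np.ndarray:
    """Train and return probability-like scores on the test block.

    SVM: linear kernel, raw decision values sigmoid-mapped to (0,1) so the
    0.5 cutoff coincides with the decision boundary.
    """
    if classifier == "svm":
        clf = SVC(kernel="linear")
        clf.fit(x_tr, y_tr)
        return special.expit(clf.decision_function(x_te))
    if classifier == "random_forest":
        clf = RandomForestClassifier(n_estimators=200, random_state=seed)
        clf.fit(x_tr, y_tr)
        return clf.predict_proba(x_te)[:, 1]
    raise ValueError(f"unknown classifier {classifier!r}")


# --------------------------------------------------------------- benchmark

@dataclass
class SelectionHistory:
    """Per-fold FeatureSets and the derived selection-frequency table."""

    sets: list[FeatureSet] = field(default_factory=list)

    def counts(self) -> Counter:
        c: Counter = Counter()
        for fs in self.sets:
            c.update(fs.features)
        return c


def fsf(history: SelectionHistory, top_k: int = 20) -> FeatureSet:
    """Frequently selected features: rank by selection count across folds."""
    counts = history.counts()
    if not counts:
        raise ValueError("empty selection history")
    order = sorted(counts, key=lambda f: (-counts[f], f))[:top_k]
    return FeatureSet(
        features=order,
        scores=[float(counts[f]) for f in order],
        algorithm="FSF",
    )


def _network_view(X: pd.DataFrame, net: Network | None, level: str) -> pd.DataFrame:
    """Restrict a level matrix to the features the network covers."""
    if net is None:
        return X
    feats = sorted({f for f in net.features_for_level(level).values()
                    if f in X.columns})
    if not feats:
        raise ValueError("network maps to no measured feature on this level")
    return X[feats]


def run_benchmark(
    data: MultiOmicsDataset,
    labels: PrognosisLabels,
    survival: SurvivalData | None,
    networks: Sequence[tuple[str, Network | None]],
    algorithms: Sequence[str],
    plan: CVPlan,
    level: str = "GE",
    classifier: str = "svm",
    k: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], SelectionHistory]]:
    """Run every (algorithm x network) cell over the shared fold plan.

    A network restricts the feature view to its mapped features (the
    phenotype-relevant feature space); network-based algorithms additionally
    use its edges.  ``networks`` entries with a ``None`` network mean the
    full feature space.  Returns the long-format record table and the
    per-cell selection histories.
    """
    y = labels.binary()
    X_full = data.levels[level].loc[y.index]
    records = []
    histories: dict[tuple[str, str], SelectionHistory] = {}
    for net_id, net in networks:
        X_view = _network_view(X_full, net, level)
        for algorithm in algorithms:
            hist = histories.setdefault((algorithm, net_id), SelectionHistory())
            use_net = net if algorithm in NETWORK_ALGORITHMS else None
            for rep, f, train, test in plan.iter_splits():
                fs = select(
                    algorithm, X_view.loc[train], y.loc[train], net=use_net,
                    k=k, seed=int_seed(seed, "select", algorithm, net_id, rep, f),
                    level=level,
                    survival=survival.loc(train) if survival is not None else None,
                )
                fs.context.update(level=level, network=net_id, repeat=rep, fold=f)
                hist.sets.append(fs)
                rec = _score_fold(
                    X_view, y, fs.features, train, test, classifier,
                    int_seed(seed, "clf", algorithm, net_id, rep, f),
                )
                rec.update(algorithm=algorithm, network=net_id, level=level,
                           repeat=rep, fold=f, n_features=len(fs))
                records.append(rec)
    return pd.DataFrame.from_records(records), histories


def _score_fold(X, y, features, train, test, classifier, seed) -> dict:
    if not features:  # selection came back empty: record chance performance
        return {"auc": 0.5, "aupr": float(y.loc[test].mean()), "accuracy": 0.5,
                "tp": 0, "fp": 0, "tn": 0, "fn": 0, "flagged": True}
    scores = _fit_score(
        X.loc[train, features].values, y.loc[train].values,
        X.loc[test, features].values, classifier, seed,
    )
    y_te = y.loc[test].values
    rec = {"auc": auc(scores, y_te), "aupr": aupr(scores, y_te),
           "accuracy": accuracy(scores, y_te), "flagged": False}
    rec.update(confusion(scores, y_te))
    return rec


def evaluate_feature_sets(
    data: MultiOmicsDataset,
    labels: PrognosisLabels,
    features: Sequence[str],
    plan: CVPlan,
    level: str = "GE",
    classifier: str = "svm",
    seed: int = 0,
    tag: str = "fixed",
) -> pd.DataFrame:
    """Score a fixed feature list over the plan (FSF / no-selection groups)."""
    y = labels.binary()
    X = data.levels[level].loc[y.index]
    feats = [f for f in features if f in X.columns]
    records = []
    for rep, f, train, test in plan.iter_splits():
        rec = _score_fold(X, y, feats, train, test, classifier,
                          int_seed(seed, "clf", tag, rep, f))
        rec.update(algorithm=tag, network="-", level=level, repeat=rep, fold=f,
                   n_features=len(feats))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def threshold_sensitivity(
    data: MultiOmicsDataset,
    survival: SurvivalData,
    networks: Sequence[tuple[str, Network | None]],
    algorithms: Sequence[str],
    n_folds: int = 10,
    n_repeats: int = 30,
    settings: dict[str, tuple[float, float]] | None = None,
    level: str = "GE",
    classifier: str = "svm",
    k: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run the benchmark under each labeling-threshold setting.

    Each setting (low_days, high_days) relabels the cohort, rebuilds the
    fold plan and reruns the full benchmark; records gain a ``thresholds``
    tag.  More discrepant thresholds define more separated classes.
    """
    from .simulate import THRESHOLD_SETTINGS, label_by_thresholds

    settings = settings or THRESHOLD_SETTINGS
    frames = []
    for name, (low, high) in settings.items():
        labels = label_by_thresholds(survival, low, high)
        plan = make_cv_plan(labels, n_folds, n_repeats,
                            seed=int_seed(seed, "plan", name))
        rec, _ = run_benchmark(data, labels, survival, networks, algorithms,
                               plan, level=level, classifier=classifier, k=k,
                               seed=int_seed(seed, "bench", name))
        frames.append(rec.assign(thresholds=name))
    return pd.concat(frames, ignore_index=True)


def comparative_groups(
    data: MultiOmicsDataset,
    labels: PrognosisLabels,
    survival: SurvivalData | None,
    net: Network,
    plan: CVPlan,
    feature_pool: Sequence[str] | None = None,
    algorithms: Sequence[str] = ("t-test",),
    n_random_networks: int = 150,
    hallmark_features: Sequence[str] | None = None,
    level: str = "GE",
    classifier: str = "svm",
    k: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """The five baseline groups against phenotype-network selection.

    1. selection on random networks (``n_random_networks`` replicates),
    2. all network features without selection,
    3. all level features without selection,
    4. Lasso on the full feature space,
    5. a provided hallmark feature list without selection.
    Records are tagged by ``group`` for downstream paired comparison.
    """
    from .network import random_network_null

    pool = list(feature_pool) if feature_pool is not None else \
        list(data.levels[level].columns)
    frames = []
    rand_nets = [
        (f"random{r:03d}",
         random_network_null(net, pool, int_seed(seed, "randnet", r)))
        for r in range(n_random_networks)
    ]
    rec, _ = run_benchmark(data, labels, survival, rand_nets, algorithms, plan,
                           level=level, classifier=classifier, k=k, seed=seed)
    frames.append(rec.assign(group="random_network"))
    net_feats = sorted({f for f in net.features_for_level(level).values()
                        if f in data.levels[level].columns})
    frames.append(
        evaluate_feature_sets(data, labels, net_feats, plan, level, classifier,
                              seed, tag="all_network_features")
        .assign(group="all_network_features")
    )
    frames.append(
        evaluate_feature_sets(data, labels, list(data.levels[level].columns),
                              plan, level, classifier, seed, tag="all_features")
        .assign(group="all_features")
    )
    rec, _ = run_benchmark(data, labels, survival, [("full_space", None)],
                           ["Lasso"], plan, level=level, classifier=classifier,
                           k=k, seed=seed)
    frames.append(rec.assign(group="lasso_full_space"))
    if hallmark_features is not None:
        frames.append(
            evaluate_feature_sets(data, labels, list(hallmark_features), plan,
                                  level, classifier, seed, tag="hallmark")
            .assign(group="hallmark")
        )
    return pd.concat(frames, ignore_index=True)
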