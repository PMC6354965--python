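"""Multiple-subset sampling (MSS) feature ranking.

Draws many uniform random feature subsets, scores each by inner
cross-validated classifier AUC, and ranks each feature by the mean AUC of
the subsets that contained it: features that systematically improve
classifiers float to the top without any model-specific assumptions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from ._base import FeatureSet, top_k

__all__ = ["mss_rank"]


def _cv_auc(x: np.ndarray, y: np.ndarray, n_splits: int, seed: int) -> float:
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in cv.split(x, y):
        clf = LinearSVC()
        clf.fit(x[tr], y[tr])
        if len(np.unique(y[te])) < 2:
            continue
        aucs.append(roc_auc_score(y[te], clf.decision_function(x[te])))
    return float(np.mean(aucs)) if aucs else 0.5


def mss_rank(
    X: pd.DataFrame,
    y: pd.Series,
    n_subsets: int = 1000,
    subset_size: int = 20,
    k: int = 20,
    seed: int = 0,
    n_inner_folds: int = 3,
) -> FeatureSet:
    """Rank features by mean inner-CV AUC over random subsets containing them."""
    if n_subsets <= 0:
        raise ValueError("n_subsets must be positive")
    if subset_size > X.shape[1]:
        raise ValueError("subset_size exceeds the number of features")
    rng = np.random.default_rng(seed)
    yv = np.asarray(y.loc[X.index].values)
    xv = X.values
    sums = np.zeros(X.shape[1])
    counts = np.zeros(X.shape[1])
    for b in range(n_subsets):
        cols = rng.choice(X.shape[1], size=subset_size, replace=False)
        auc = _cv_auc(xv[:, cols], yv, n_inner_folds, int(rng.integers(2**31)))
        sums[cols] += auc
        counts[cols] += 1
    with np.errstate(invalid="ignore"):
        scores = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return top_k(list(X.columns), scores, k, "MSS")
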