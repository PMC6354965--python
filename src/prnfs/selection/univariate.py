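"""Univariate filters: Welch t ranking and single-covariate Cox PH.

The Cox fit is a hand-written one-dimensional Newton maximization of the
Breslow partial likelihood.  It is written here (rather than calling a
survival library per feature) because subnetwork search evaluates it
thousands of times per cross-validation fold; tests cross-check it against
lifelines and a grid oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from ..simulate import SurvivalData
from ._base import FeatureSet, top_k

__all__ = ["welch_t", "ttest_rank", "cox_univariate", "cox_rank"]


def welch_t(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Welch two-sample t statistic per column (0 where both groups are flat)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("y must contain exactly two classes")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(b, a, axis=0, equal_var=False).statistic
    return np.nan_to_num(np.asarray(t, dtype=float))


def ttest_rank(X: pd.DataFrame, y: pd.Series, k: int = 20) -> FeatureSet:
    """Rank features by |Welch t| between the two label groups."""
    t = welch_t(X.values, y.loc[X.index].values)
    return top_k(list(X.columns), np.abs(t), k, "t-test")


def _breslow_parts(x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Sort descending by time and locate Breslow risk-set boundaries."""
    order = np.argsort(-time, kind="stable")
    t, xs, es = time[order], x[order], event[order]
    # risk set of a death at t_i = all samples with time >= t_i; with the
    # descending sort that is the prefix up to the last index tied with t_i
    riskend = np.arange(len(t))
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] == t[i]:
            j += 1
        riskend[i : j + 1] = j
        i = j + 1
    return xs, es.astype(bool), riskend


def cox_univariate(
    x: np.ndarray | pd.Series, surv: SurvivalData, max_iter: int = 50, tol: float = 1e-9
) -> tuple[float, float, float]:
    """Single-covariate Cox PH fit with Breslow tie handling.

    Returns ``(coefficient, wald_z, two_sided_p)``.  A constant covariate
    returns ``(0, 0, 1)`` by convention.
    """
    if isinstance(x, pd.Series):
        x = x.loc[surv.samples].values
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate must be finite")
    if surv.event.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.ptp(x) == 0:
        return 0.0, 0.0, 1.0
    x = (x - x.mean()) / max(x.std(), 1e-12)
    xs, es, riskend = _breslow_parts(
        x, surv.time.values.astype(float), surv.event.values.astype(int)
    )

    def score_info(beta: float) -> tuple[float, float, float]:
        eta = np.clip(beta * xs, -500, 500)
        w = np.exp(eta)
        cw = np.cumsum(w)[riskend]
        cwx = np.cumsum(w * xs)[riskend]
        cwxx = np.cumsum(w * xs * xs)[riskend]
        mean = cwx / cw
        ll = float(np.sum(eta[es] - np.log(cw[es])))
        u = float(np.sum(xs[es] - mean[es]))
        info = float(np.sum(cwxx[es] / cw[es] - mean[es] ** 2))
        return ll, u, info

    beta = 0.0
    ll, u, info = score_info(beta)
    for _ in range(max_iter):
        if info <= 0:
            break
        step = u / info
        new = beta + step
        ll_new, u_new, info_new = score_info(new)
        halvings = 0
        while (not np.isfinite(ll_new) or ll_new < ll - 1e-12) and halvings < 30:
            step /= 2.0
            new = beta + step
            ll_new, u_new, info_new = score_info(new)
            halvings += 1
        beta, ll, u, info = new, ll_new, u_new, info_new
        if abs(step) < tol and abs(u) < 1e-6:
            break
    else:
        if abs(u) > 1e-3:
            raise RuntimeError("univariate Cox fit did not converge")
    if info <= 0:
        return float(beta), 0.0, 1.0
    z = beta * np.sqrt(info)
    p = float(2.0 * special.ndtr(-abs(z)))
    return float(beta), float(z), p


def cox_rank(X: pd.DataFrame, surv: SurvivalData, k: int = 20) -> FeatureSet:
    """Rank features by univariate Cox |Wald z|."""
    sub = surv.loc(X.index)
    zs = np.array([abs(cox_univariate(X[c], sub)[1]) for c in X.columns])
    return top_k(list(X.columns), zs, k, "Cox")
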