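"""Sparse regression selectors: Lasso, network-constrained Lasso, L1 Cox.

NetLasso minimizes

    (1/2n) ||y - X w||^2 + alpha * [ lambda ||w||_1
        + (1 - lambda) * sum_{i<j} A_ij (w_i - w_j)^2 ]

i.e. an L1 penalty mixed with a graph-Laplacian quadratic that forces
adjacent nodes toward similar weights.  The quadratic term is folded into
an augmented least-squares design (rows sqrt(A_ij) (e_i - e_j)), so the
whole problem is solved with coordinate-descent Lasso; features unmapped to
any network node receive only the L1 term automatically.  The L1-penalized
Cox path is delegated to scikit-survival's Coxnet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ..network import Network
from ..simulate import SurvivalData
from ._base import FeatureSet, top_k

__all__ = ["NetLassoConfig", "lasso_select", "netlasso_fit", "netlasso_select",
           "regcox_select"]


@dataclass
class NetLassoConfig:
    alpha: float = 0.1
    lambda_mix: float = 0.5
    level: str = "GE"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 <= self.lambda_mix <= 1:
            raise ValueError("lambda_mix must lie in [0, 1]")


def _signed_labels(y: pd.Series, index: pd.Index) -> np.ndarray:
    yv = np.asarray(y.loc[index].values)
    classes = np.unique(yv)
    if classes.size != 2:
        raise ValueError("y must contain exactly two classes")
    return np.where(yv == classes[1], 1.0, -1.0)


def lasso_select(X: pd.DataFrame, y: pd.Series, k: int = 20) -> FeatureSet:
    """Smallest L1 penalty on the path with <= k active features.

    Squared loss on +/-1 labels; features ordered by |coefficient| at the
    chosen penalty.
    """
    if k <= 0:
        return FeatureSet([], [], "Lasso")
    yv = _signed_labels(y, X.index)
    alphas, coefs, _ = lasso_path(X.values, yv, alphas=100, eps=1e-3)
    nnz = (np.abs(coefs) > 1e-12).sum(axis=0)
    admissible = np.nonzero(nnz <= k)[0]
    idx = int(admissible[-1]) if admissible.size else 0  # alphas are decreasing
    w = coefs[:, idx]
    active = np.abs(w) > 1e-12
    ids = [c for c, a in zip(X.columns, active) if a]
    return top_k(ids, np.abs(w[active]), k, "Lasso")


def _laplacian_rows(
    columns: pd.Index, net: Network, level: str
) -> np.ndarray:
    """Incidence-style rows B with B^T B = graph Laplacian over mapped columns."""
    col_idx = {c: j for j, c in enumerate(columns)}
    rows = []
    for u, v, w in net.graph.edges(data="weight", default=1.0):
        fu, fv = net.feature_for(u, level), net.feature_for(v, level)
        if fu in col_idx and fv in col_idx and fu != fv:
            row = np.zeros(len(columns))
            row[col_idx[fu]] = np.sqrt(w)
            row[col_idx[fv]] = -np.sqrt(w)
            rows.append(row)
    return np.array(rows) if rows else np.empty((0, len(columns)))


def netlasso_fit(
    X: pd.DataFrame, y: pd.Series, net: Network, cfg: NetLassoConfig
) -> pd.Series:
    """Network-constrained Lasso weights at a fixed (alpha, lambda_mix).

    Implemented by augmenting the design with scaled Laplacian incidence
    rows and zero responses, which reproduces the stated objective exactly
    up to an overall positive factor (so the minimizer is unchanged).
    """
    yv = _signed_labels(y, X.index)
    n = len(yv)
    b = _laplacian_rows(X.columns, net, cfg.level)
    quad = cfg.alpha * (1.0 - cfg.lambda_mix)
    if len(b) and quad > 0:
        x_aug = np.vstack([X.values, np.sqrt(2.0 * n * quad) * b])
        y_aug = np.concatenate([yv, np.zeros(len(b))])
    else:
        x_aug, y_aug = X.values, yv
    n_aug = len(y_aug)
    l1 = cfg.alpha * cfg.lambda_mix * n / n_aug
    if l1 > 1e-12:
        model = Lasso(alpha=l1, fit_intercept=False, max_iter=100_000, tol=1e-10)
        model.fit(x_aug, y_aug)
        w = model.coef_
    else:  # pure quadratic penalty: augmented least squares
        w, *_ = np.linalg.lstsq(x_aug, y_aug, rcond=None)
    return pd.Series(w, index=X.columns, name="weight")


def netlasso_select(
    X: pd.DataFrame,
    y: pd.Series,
    net: Network,
    k: int = 20,
    lambda_mix: float = 0.5,
    level: str = "GE",
    n_alphas: int = 30,
) -> FeatureSet:
    """NetLasso over a geometric alpha grid; smallest alpha with <= k active."""
    if k <= 0:
        return FeatureSet([], [], "NetLasso")
    yv = _signed_labels(y, X.index)
    n = len(yv)
    a_max = np.max(np.abs(X.values.T @ yv)) / (n * max(lambda_mix, 1e-3))
    best = None
    for alpha in np.geomspace(a_max, a_max * 1e-3, n_alphas):
        w = netlasso_fit(X, y, net, NetLassoConfig(alpha, lambda_mix, level))
        nnz = int((w.abs() > 1e-12).sum())
        if nnz <= k:
            best = w
        else:
            break
    if best is None or (best.abs() > 1e-12).sum() == 0:
        best = w  # fall back to the densest fit tried
    active = best[best.abs() > 1e-12]
    return top_k(list(active.index), active.abs().values, k, "NetLasso")


def regcox_select(X: pd.DataFrame, surv: SurvivalData, k: int = 20) -> FeatureSet:
    """L1-penalized Cox path; smallest penalty with <= k active features."""
    if k <= 0:
        return FeatureSet([], [], "RegCox")
    sub = surv.loc(X.index)
    if sub.event.sum() < 2:
        raise ValueError("need at least 2 events")
    y = Surv.from_arrays(sub.event.values.astype(bool), sub.time.values)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=100, alpha_min_ratio=0.01, fit_baseline_model=False
    )
    model.fit(X.values, y)
    coefs = model.coef_  # (n_features, n_alphas), alphas decreasing
    nnz = (np.abs(coefs) > 1e-12).sum(axis=0)
    admissible = np.nonzero(nnz <= k)[0]
    idx = int(admissible[-1]) if admissible.size else 0
    w = coefs[:, idx]
    active = np.abs(w) > 1e-12
    ids = [c for c, a in zip(X.columns, active) if a]
    return top_k(ids, np.abs(w[active]), k, "RegCox")
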