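"""Single-response partial least squares regression via NIPALS.

NIPALS for one response converges in a single pass per component: the weight
is w ∝ Xᵀy (unit norm), the score t = Xw, the loadings p = Xᵀt/tᵀt and
q = yᵀt/tᵀt, followed by deflation X ← X − tpᵀ, y ← y − qt.  Regression
coefficients on centered data are β = W(PᵀW)⁻¹q.

Latent-variable (LV) count is chosen by leave-one-out cross-validation
(LOOCV).  The LOOCV engine refits every fold from scratch — centering
included — but is vectorised across folds, which keeps full-grid screening
(p ≈ 850, n = 70, 15 LVs) at sub-second cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class RankDeficiencyError(np.linalg.LinAlgError):
    """y is orthogonal to the deflated X before the requested LV count."""

    def __init__(self, component: int):
        self.component = component
        super().__init__(
            f"rank exhausted at component {component}: remaining X carries no covariance with y"
        )


@dataclass
class PLSRModel:
    """Fitted PLS1 model with centering constants and factor decomposition."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # p x A
    x_loadings: np.ndarray   # p x A
    y_loadings: np.ndarray   # A
    scores: np.ndarray       # n x A (training scores)
    n_lv: int
    beta: np.ndarray         # p, coefficients on centered data
    intercept: float

    @property
    def n_features(self) -> int:
        return self.beta.size


@dataclass
class CVResult:
    """LOOCV curve over LV counts and the selected optimum."""

    rmsecv_by_lv: np.ndarray
    optimal_lv: int
    r_cv: float
    cv_predictions: np.ndarray = field(repr=False, default=None)
    truncated_at: int | None = None


def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSRModel:
    """Fit a PLS1 model with ``n_lv`` components (mean-centering only)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size}")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}]")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale = np.linalg.norm(Xc.T @ yc) + np.finfo(float).tiny

    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    T = np.empty((n, n_lv))
    for a in range(n_lv):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale:
            raise RankDeficiencyError(a + 1)
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= np.finfo(float).tiny:
            raise RankDeficiencyError(a + 1)
        pl = Xc.T @ t / tt
        ql = float(yc @ t / tt)
        Xc -= np.outer(t, pl)
        yc = yc - ql * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pl, ql, t

    beta = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ beta)
    return PLSRModel(x_mean, y_mean, W, P, q, T, n_lv, beta, intercept)


def predict(m: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses; equals ŷ = (X − x̄)β + ȳ."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != m.n_features:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {m.n_features}"
        )
    return X_new @ m.beta + m.intercept


def loocv_predictions(X: np.ndarray, y: np.ndarray, a_max: int) -> tuple[np.ndarray, int]:
    """Held-out predictions for every sample at every LV count 1..a_max.

    Returns ``(preds, a_reached)`` where ``preds[i, a-1]`` is the prediction
    of sample ``i`` by a model trained on the other n−1 samples with ``a``
    components.  If some fold exhausts rank before ``a_max``, the curve is
    truncated at the last component reached by every fold.

    All folds are advanced together: fold-deleted matrices are stacked into a
    3-D tensor and each NIPALS step becomes a batched matmul.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    a_max = min(a_max, n - 2, p)
    if a_max < 1:
        raise ValueError("not enough samples/features for LOOCV")

    # row i of idx = all sample indices except i
    idx = (np.arange(n)[:, None] + np.arange(1, n)[None, :]) % n
    Xf = X[idx]                       # (n, n-1, p)
    yf = y[idx]                       # (n, n-1)
    xm = Xf.mean(axis=1)
    ym = yf.mean(axis=1)
    Xc = Xf - xm[:, None, :]
    yc = yf - ym[:, None]
    xh = X - xm                       # centered held-out rows

    scale = np.linalg.norm(np.einsum("fn,fnp->fp", yc, Xc), axis=1).max() + np.finfo(float).tiny
    preds = np.empty((n, a_max))
    pred = ym.copy()
    a_reached = a_max
    for a in range(a_max):
        w = np.matmul(yc[:, None, :], Xc)[:, 0, :]          # (f, p)
        nw = np.linalg.norm(w, axis=1)
        if np.any(nw <= 1e-12 * scale):
            a_reached = a
            break
        w /= nw[:, None]
        t = np.matmul(Xc, w[:, :, None])[:, :, 0]            # (f, n-1)
        tt = np.einsum("fn,fn->f", t, t)
        if np.any(tt <= np.finfo(float).tiny):
            a_reached = a
            break
        pl = np.matmul(t[:, None, :], Xc)[:, 0, :] / tt[:, None]
        ql = np.einsum("fn,fn->f", yc, t) / tt
        Xc -= t[:, :, None] * pl[:, None, :]
        yc -= ql[:, None] * t
        t_new = np.einsum("fp,fp->f", xh, w)
        pred = pred + ql * t_new
        xh = xh - t_new[:, None] * pl
        preds[:, a] = pred
    if a_reached < 1:
        raise RankDeficiencyError(1)
    return preds[:, :a_reached], a_reached


def loocv_select_lv(X: np.ndarray, y: np.ndarray, a_max: int = 15) -> CVResult:
    """RMSECV per LV count and the optimum (global minimum, smallest-A ties).

    Centering is recomputed inside each fold.  The preprocessing operators in
    this package are per-sample, so applying them before the loop is
    equivalent to applying them inside it.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    requested = min(a_max, n - 2, np.asarray(X).shape[1])
    preds, a_reached = loocv_predictions(X, y, a_max)
    rmsecv = np.sqrt(np.mean((y[:, None] - preds) ** 2, axis=0))
    optimal = int(np.argmin(rmsecv)) + 1   # argmin returns the first minimum
    cv_opt = preds[:, optimal - 1]
    denom = np.std(y) * np.std(cv_opt)
    r_cv = float(np.corrcoef(y, cv_opt)[0, 1]) if denom > 0 else 0.0
    return CVResult(
        rmsecv_by_lv=rmsecv,
        optimal_lv=optimal,
        r_cv=r_cv,
        cv_predictions=cv_opt,
        truncated_at=a_reached if a_reached < requested else None,
    )
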