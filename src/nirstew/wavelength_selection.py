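"""Informative-wavelength selection from PLSR models.

Two methods:

* **RC** — rank the local extrema (peaks and valleys) of the regression
  coefficient curve β(λ) by |β| and keep the strongest.  Wavelengths between
  extrema are never selected: an extremum marks the center of an absorption
  feature driving the model.
* **Random frog (RF)** — a reversible-jump MCMC-style chain over variable
  subsets.  Each iteration proposes a new subset size from a normal
  distribution around the current size, shrinks or grows the subset using
  |β| of a PLS submodel, and accepts the candidate based on its LOOCV
  RMSECV.  A variable's importance is the fraction of iterations it spent in
  the accepted subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .plsr import PLSRModel, RankDeficiencyError, fit_plsr, loocv_predictions

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Selected wavelengths plus the full per-wavelength importance curve."""

    method: str                    # "RC" or "RF"
    selected_nm: np.ndarray        # sorted ascending, subset of grid_nm
    grid_nm: np.ndarray
    importance: np.ndarray         # |β| at extrema (RC) or selection prob (RF), per grid point
    n_requested: int
    seed: int | None = None
    shortfall: bool = False

    @property
    def selected_indices(self) -> np.ndarray:
        return np.searchsorted(self.grid_nm, self.selected_nm)


@dataclass
class RFParams:
    """Random-frog chain parameters.

    ``n_iterations`` is the chain length N.  ``q_init`` is the initial subset
    size, ``theta`` the relative SD of the proposed subset size, ``omega`` the
    oversampling multiplier when growing, ``eta`` the acceptance damping for
    worse candidates, and ``max_lv_submodel`` caps each submodel's LV count
    (the submodel's own LOOCV chooses within the cap).
    """

    n_iterations: int = 1000
    q_init: int = 10
    theta: float = 0.3
    omega: int = 3
    eta: float = 0.1
    max_lv_submodel: int = 5

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.q_init < 1:
            raise ValueError("q_init must be >= 1")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")


def _local_extrema(beta: np.ndarray) -> np.ndarray:
    """Interior indices where β has a sign-aware peak or valley."""
    left = beta[1:-1] - beta[:-2]
    right = beta[1:-1] - beta[2:]
    peaks = (left > 0) & (right >= 0)
    valleys = (left < 0) & (right <= 0)
    return np.flatnonzero(peaks | valleys) + 1


def select_by_rc(m: PLSRModel, grid: np.ndarray, n_sel: int) -> SelectionResult:
    """Top-``n_sel`` local extrema of the regression-coefficient curve by |β|."""
    grid = np.asarray(grid, dtype=float)
    if grid.size != m.n_features:
        raise ValueError("grid length does not match the fitted model")
    if n_sel < 1:
        raise ValueError("n_sel must be >= 1")
    ext = _local_extrema(m.beta)
    importance = np.zeros(grid.size)
    importance[ext] = np.abs(m.beta[ext])
    shortfall = ext.size < n_sel
    if shortfall:
        chosen = ext
    else:
        order = ext[np.argsort(-np.abs(m.beta[ext]), kind="stable")]
        chosen = order[:n_sel]
    return SelectionResult(
        method="RC",
        selected_nm=np.sort(grid[chosen]),
        grid_nm=grid,
        importance=importance,
        n_requested=n_sel,
        shortfall=shortfall,
    )


def _submodel_rmsecv(X: np.ndarray, y: np.ndarray, cols: np.ndarray, cap: int) -> float:
    """Best LOOCV RMSECV of a PLS submodel on ``cols``, LVs chosen up to ``cap``."""
    a_max = min(cap, cols.size, y.size - 2)
    preds, _ = loocv_predictions(X[:, cols], y, a_max)
    return float(np.sqrt(np.mean((y[:, None] - preds) ** 2, axis=0)).min())


def _rank_by_beta(X: np.ndarray, y: np.ndarray, cols: np.ndarray, cap: int) -> np.ndarray:
    """Columns sorted by decreasing |β| of a PLS fit on ``cols``."""
    n_lv = min(cap, cols.size, y.size - 1)
    m = fit_plsr(X[:, cols], y, n_lv)
    order = np.argsort(-np.abs(m.beta), kind="stable")
    return cols[order]


def random_frog(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    params: RFParams | None = None,
    n_sel: int = 10,
    seed: int | None = None,
) -> SelectionResult:
    """Random-frog selection probabilities over ``params.n_iterations`` iterations.

    The chain state is a variable subset.  A candidate subset size q* is
    drawn from N(q, (θq)²), rounded and clipped to [1, p].  Shrinking keeps
    the q* current variables with the largest |β|; growing adds
    min(ω·(q*−q), p−q) uniformly drawn outsiders before |β|-truncation back
    to q*.  The candidate replaces the state if its LOOCV RMSECV is no worse,
    otherwise with probability η·(RMSECV_current / RMSECV_candidate).
    Acceptance only ever sees the matrix passed in — selection must be run on
    calibration rows so the prediction set stays untouched.
    """
    params = params or RFParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float)
    n, p = X.shape
    if grid.size != p:
        raise ValueError("grid length does not match X")
    if p < params.q_init:
        raise ValueError("q_init exceeds the number of variables")
    if n < 6:
        raise ValueError("random frog needs at least 6 samples")

    rng = np.random.default_rng(seed)
    cap = params.max_lv_submodel
    subset = np.sort(rng.choice(p, size=params.q_init, replace=False))
    current_rmsecv = _submodel_rmsecv(X, y, subset, cap)

    counts = np.zeros(p)
    n_rejected_degenerate = 0
    for _ in range(params.n_iterations):
        q = subset.size
        q_star = int(np.clip(np.rint(rng.normal(q, params.theta * q)), 1, p))
        try:
            if q_star <= q:
                candidate = np.sort(_rank_by_beta(X, y, subset, cap)[:q_star])
            else:
                outside = np.setdiff1d(np.arange(p), subset, assume_unique=False)
                n_new = min(params.omega * (q_star - q), outside.size)
                extras = rng.choice(outside, size=n_new, replace=False)
                union = np.concatenate([subset, extras])
                candidate = np.sort(_rank_by_beta(X, y, union, cap)[:q_star])
            cand_rmsecv = _submodel_rmsecv(X, y, candidate, cap)
        except RankDeficiencyError:
            n_rejected_degenerate += 1
            counts[subset] += 1
            continue
        if cand_rmsecv <= current_rmsecv or rng.random() < params.eta * (
            current_rmsecv / cand_rmsecv
        ):
            subset, current_rmsecv = candidate, cand_rmsecv
        counts[subset] += 1
    if n_rejected_degenerate:
        logger.warning("random frog rejected %d degenerate submodels", n_rejected_degenerate)

    prob = counts / params.n_iterations
    n_sel_eff = min(n_sel, p)
    top = np.argsort(-prob, kind="stable")[:n_sel_eff]
    return SelectionResult(
        method="RF",
        selected_nm=np.sort(grid[top]),
        grid_nm=grid,
        importance=prob,
        n_requested=n_sel,
        seed=seed,
        shortfall=n_sel_eff < n_sel,
    )
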