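"""Calibration diagnostics: R/RMSE, RPD, descriptive stats, Pearson matrix, splits."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import ReferenceTable


@dataclass
class EvaluationReport:
    """Full metric set for one (trait, band, preprocessing) model.

    RMSE values are in g/kg; R and RPD are dimensionless.
    """

    trait: str
    band: str
    preprocessing: str
    n_lv: int
    r_c: float
    rmsec: float
    r_cv: float
    rmsecv: float
    r_p: float
    rmsep: float
    rpd: float


@dataclass
class SplitSpec:
    """Disjoint calibration/prediction id partition."""

    calibration_ids: list[str]
    prediction_ids: list[str]
    seed: int


@dataclass
class DescriptiveStats:
    mean: float
    sd: float
    minimum: float
    maximum: float
    cv_percent: float


def regression_metrics(y_ref: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Pearson R between reference and predicted values, and RMSE (denominator n)."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_ref.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_ref.size} vs {y_pred.size}")
    if y_ref.size < 2:
        raise ValueError("need at least 2 observations")
    if np.std(y_ref) == 0:
        raise ValueError("constant reference values: R undefined")
    rmse = float(np.sqrt(np.mean((y_ref - y_pred) ** 2)))
    if np.std(y_pred) == 0:
        r = 0.0  # degenerate predictions carry no correlation
    else:
        r = float(np.corrcoef(y_ref, y_pred)[0, 1])
    return r, rmse


def rpd(sd_prediction_set: float, rmsep: float) -> float:
    """Ratio of the prediction set's SD to RMSEP."""
    if sd_prediction_set <= 0 or rmsep <= 0:
        raise ValueError("RPD needs positive SD and RMSEP")
    return float(sd_prediction_set / rmsep)


def rpd_label(value: float) -> str:
    """Conventional reliability bands: <1.5 inadequate, >=2.5 good, >5 analytical."""
    if value < 1.5:
        return "inadequate"
    if value < 2.5:
        return "fair"
    if value <= 5:
        return "good"
    return "analytical"


def descriptive_stats(values: Sequence[float]) -> DescriptiveStats:
    """Mean, SD (n−1), range, and CV% = 100·SD/mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = 100.0 * sd / mean if mean > 0 else float("nan")
    return DescriptiveStats(mean, sd, float(v.min()), float(v.max()), cv)


def pearson_significance(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r via t = r·sqrt((n−2)/(1−r²))."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def significance_flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_matrix(refs: ReferenceTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r between traits with ``**``/``*`` significance flags.

    Returns ``(r, flags)`` DataFrames; a constant trait yields NaN entries.
    """
    names = list(refs.traits)
    n = refs.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples")
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    flags = pd.DataFrame("", index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            va, vb = refs.traits[a], refs.traits[b]
            if np.std(va) == 0 or np.std(vb) == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                continue
            rr = float(np.corrcoef(va, vb)[0, 1])
            fl = significance_flag(pearson_significance(rr, n))
            r.loc[a, b] = r.loc[b, a] = rr
            flags.loc[a, b] = flags.loc[b, a] = fl
    return r, flags


def random_split(ids: Sequence[str], n_cal: int, seed: int) -> SplitSpec:
    """Uniform random calibration/prediction partition, deterministic per seed."""
    ids = [str(s) for s in ids]
    if not 0 < n_cal < len(ids):
        raise ValueError(f"n_cal must be in (0, {len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    cal = sorted(ids[i] for i in perm[:n_cal])
    pred = sorted(ids[i] for i in perm[n_cal:])
    return SplitSpec(cal, pred, seed)
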