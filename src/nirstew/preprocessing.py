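"""Spectral preprocessing: SNV, SNV+detrend, and Savitzky-Golay derivatives.

All operators act row-wise (per spectrum) and are therefore safe to apply
before a cross-validation split: no statistic is pooled across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import SpectraSet, SpectraValidationError, GridMismatchError

PREPROC_NAMES = ("none", "snv", "snvd", "der1", "der2")


class DegenerateSpectrumError(ValueError):
    """A spectrum has zero variance and cannot be SNV-normalised."""


@dataclass
class PreprocSpec:
    """Choice and parameters of a preprocessing operator.

    ``name`` is one of ``none | snv | snvd | der1 | der2``.  The derivative
    operators use a Savitzky-Golay fit of order ``sg_polyorder`` (default 2)
    in a moving window of ``sg_window`` points (default 15); ``snvd`` detrends
    with a polynomial of degree ``detrend_degree`` (default 2) after SNV.
    """

    name: str = "none"
    sg_window: int = 15
    sg_polyorder: int = 2
    detrend_degree: int = 2

    def __post_init__(self) -> None:
        name = self.name.lower()
        if name not in PREPROC_NAMES:
            raise ValueError(f"unknown preprocessing '{self.name}'")
        self.name = name
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")
        if self.detrend_degree < 1:
            raise ValueError("detrend_degree must be >= 1")


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-row centering and unit scaling.

    Removes multiplicative scatter and additive offset; each output row has
    mean 0 and standard deviation 1 (n-1 convention).
    """
    if s.n_wavelengths < 2:
        raise SpectraValidationError("SNV needs at least two wavelengths")
    mu = s.values.mean(axis=1, keepdims=True)
    sd = s.values.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise DegenerateSpectrumError(
            f"zero-variance spectrum for sample '{s.sample_ids[flat[0]]}'"
        )
    return s.with_values((s.values - mu) / sd)


def detrend(s: SpectraSet, degree: int = 2) -> SpectraSet:
    """Remove a per-row least-squares polynomial (in nm) from each spectrum."""
    if degree >= s.n_wavelengths - 1:
        raise SpectraValidationError(
            f"detrend degree {degree} underdetermined on {s.n_wavelengths} wavelengths"
        )
    # Shared Vandermonde in a scaled coordinate for conditioning; the fitted
    # subspace (polynomials of degree <= d in nm) is unchanged by scaling.
    lam = s.wavelengths_nm
    span = np.ptp(lam)
    x = (lam - lam.mean()) / (span / 2 if span > 0 else 1.0)
    V = np.vander(x, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, s.values.T, rcond=None)
    return s.with_values(s.values - (V @ coef).T)


def snvd(s: SpectraSet, spec: PreprocSpec | None = None) -> SpectraSet:
    """SNV followed by polynomial detrend (Barnes-style SNV-detrend)."""
    degree = (spec or PreprocSpec(name="snvd")).detrend_degree
    return detrend(snv(s), degree)


def savgol_derivative(s: SpectraSet, spec: PreprocSpec, deriv_order: int) -> SpectraSet:
    """Savitzky-Golay derivative scaled by the physical pitch (per nm^order).

    Requires a uniform grid (1% relative tolerance on the pitch).  The
    half-window at each edge is dropped rather than extrapolated, so the
    output grid loses ``(sg_window - 1) / 2`` points per side.
    """
    if deriv_order not in (1, 2):
        raise ValueError("deriv_order must be 1 or 2")
    if s.n_wavelengths < spec.sg_window:
        raise SpectraValidationError(
            f"SG window {spec.sg_window} exceeds spectrum length {s.n_wavelengths}"
        )
    pitch = np.diff(s.wavelengths_nm)
    mean_pitch = pitch.mean()
    if np.any(np.abs(pitch - mean_pitch) > 0.01 * mean_pitch):
        raise GridMismatchError("SG derivative needs a uniform wavelength grid")
    out = savgol_filter(
        s.values,
        window_length=spec.sg_window,
        polyorder=spec.sg_polyorder,
        deriv=deriv_order,
        delta=mean_pitch,
        axis=1,
    )
    half = (spec.sg_window - 1) // 2
    return s.with_values(out[:, half:-half], s.wavelengths_nm[half:-half])


def apply_preprocessing(s: SpectraSet, spec: PreprocSpec) -> SpectraSet:
    """Dispatch by ``spec.name``; ``none`` returns the input unchanged."""
    if spec.name == "none":
        return s
    if spec.name == "snv":
        return snv(s)
    if spec.name == "snvd":
        return snvd(s, spec)
    if spec.name == "der1":
        return savgol_derivative(s, spec, 1)
    return savgol_derivative(s, spec, 2)
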