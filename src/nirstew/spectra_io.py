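"""Containers and I/O for dual-band reflectance spectra and reference chemistry.

Spectral matrices are stored wide (rows = samples, columns = wavelengths in
nm), matching typical spectrometer CSV exports.  Reference chemistry is a per
sample table of the five meat quality traits (fat, protein, collagen, ash,
Na), all in g/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TRAITS = ("fat", "protein", "collagen", "ash", "Na")

#: Band-trimming intervals used throughout: the instrument ranges minus the
#: high-noise edges (below 650 nm, the 942.7-960 nm gap, above 1650 nm).
VNIR_KEEP = (650.0, 950.0)
NIR_KEEP = (960.0, 1650.0)


class SpectraFormatError(ValueError):
    """A CSV does not have the expected wide spectral layout."""


class SpectraValidationError(ValueError):
    """Structurally valid input that violates a content invariant."""


class GridMismatchError(ValueError):
    """Two spectra sets expected to share a wavelength grid do not."""


@dataclass
class SpectraSet:
    """A sample x wavelength matrix with an explicit nm grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelength grid in nm.
    values
        Reflectance (or transformed) intensities, shape
        ``(n_samples, n_wavelengths)``.
    band_label
        Identity of the band, e.g. ``"VNIR"``, ``"NIR"`` or ``"merged"``.
    sample_ids
        Unique per-row identifiers.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    band_label: str
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths_nm.ndim != 1:
            raise SpectraValidationError("wavelength grid must be 1-D")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise SpectraValidationError(
                "wavelength grid must be strictly increasing with no duplicates"
            )
        if self.values.shape != (len(self.sample_ids), self.wavelengths_nm.size):
            raise SpectraValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {self.wavelengths_nm.size} wavelengths"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectraValidationError("duplicate sample ids")
        if not np.all(np.isfinite(self.wavelengths_nm)):
            raise SpectraValidationError("non-finite wavelength")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise SpectraValidationError(
                f"non-finite intensity for sample '{self.sample_ids[bad[0]]}' "
                f"at {self.wavelengths_nm[bad[1]]:g} nm"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths_nm.size

    def with_values(self, values: np.ndarray, wavelengths_nm: np.ndarray | None = None) -> "SpectraSet":
        """Copy with new intensities (and optionally a new grid)."""
        grid = self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm
        return SpectraSet(grid, values, self.band_label, list(self.sample_ids))


@dataclass
class ReferenceTable:
    """Per-sample reference values (g/kg) for the five quality traits."""

    sample_ids: list[str]
    traits: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectraValidationError("duplicate sample ids in reference table")
        clean: dict[str, np.ndarray] = {}
        for name, vec in self.traits.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (len(self.sample_ids),):
                raise SpectraValidationError(
                    f"trait '{name}' length {v.size} != {len(self.sample_ids)} samples"
                )
            if not np.all(np.isfinite(v)):
                raise SpectraValidationError(f"non-finite value in trait '{name}'")
            if np.any(v < 0):
                raise SpectraValidationError(f"negative value in trait '{name}'")
            clean[name] = v
        self.traits = clean

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, **self.traits}).set_index(
            "sample_id"
        )

    def subset(self, ids: Sequence[str]) -> "ReferenceTable":
        """Row subset in the order of ``ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return ReferenceTable(list(ids), {k: v[idx] for k, v in self.traits.items()})


@dataclass
class BandSpec:
    """Closed keep-intervals defining a usable band after noise trimming."""

    keep_ranges: list[tuple[float, float]]
    label: str

    def __post_init__(self) -> None:
        ranges = sorted((float(a), float(b)) for a, b in self.keep_ranges)
        for lo, hi in ranges:
            if not lo < hi:
                raise SpectraValidationError(f"degenerate keep interval ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(ranges, ranges[1:]):
            if lo2 <= hi:
                raise SpectraValidationError("overlapping keep intervals")
        self.keep_ranges = ranges


def read_spectra_csv(path: str | Path, band_label: str) -> SpectraSet:
    """Read a wide spectral CSV (``sample_id,<nm>,<nm>,...``).

    Columns are sorted ascending by wavelength; malformed headers, duplicate
    sample ids and missing cells are rejected.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise SpectraFormatError(f"{path}: need a sample-id column plus wavelengths")
    try:
        nm = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavelength header: {exc}") from exc
    ids = df.iloc[:, 0].tolist()
    if df.iloc[:, 0].isna().any() or len(set(ids)) != len(ids):
        raise SpectraValidationError(f"{path}: missing or duplicate sample id")
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(mat).any():
        r, c = np.argwhere(np.isnan(mat))[0]
        raise SpectraValidationError(
            f"{path}: empty/non-numeric cell for sample '{ids[r]}' at column {nm[c]:g}"
        )
    order = np.argsort(nm)
    return SpectraSet(nm[order], mat[:, order], band_label, ids)


def write_spectra_csv(s: SpectraSet, path: str | Path) -> None:
    df = pd.DataFrame(s.values, columns=[repr(float(w)) for w in s.wavelengths_nm])
    df.insert(0, "sample_id", s.sample_ids)
    df.to_csv(path, index=False)


def read_reference_csv(path: str | Path) -> ReferenceTable:
    """Read ``sample_id,fat,protein,collagen,ash,Na`` (g/kg)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [t for t in TRAITS if t not in df.columns]
    if "sample_id" not in df.columns or missing:
        raise SpectraFormatError(f"{path}: missing columns {['sample_id'] * ('sample_id' not in df.columns) + missing}")
    return ReferenceTable(
        df["sample_id"].tolist(), {t: df[t].to_numpy(dtype=float) for t in TRAITS}
    )


def write_reference_csv(refs: ReferenceTable, path: str | Path) -> None:
    refs.to_frame().to_csv(path)


def trim_noise_bands(raw: SpectraSet, spec: BandSpec) -> SpectraSet:
    """Drop wavelengths outside every keep interval (closed endpoints)."""
    nm = raw.wavelengths_nm
    keep = np.zeros(nm.size, dtype=bool)
    for lo, hi in spec.keep_ranges:
        keep |= (nm >= lo) & (nm <= hi)
    if not keep.any():
        raise SpectraValidationError(
            f"trimming with '{spec.label}' leaves an empty band"
        )
    return SpectraSet(nm[keep], raw.values[:, keep], raw.band_label, list(raw.sample_ids))


def average_replicates(stack: Sequence[SpectraSet]) -> SpectraSet:
    """Element-wise mean of replicate measurements of the same samples.

    Measurement replicates (repeat scans, probe positions) share a grid and
    sample ids; the mean is associative, so hierarchical averaging (position
    means of repeat means) equals one joint pass.
    """
    if len(stack) == 0:
        raise SpectraValidationError("no replicate sets given")
    first = stack[0]
    for s in stack[1:]:
        if s.wavelengths_nm.shape != first.wavelengths_nm.shape or not np.allclose(
            s.wavelengths_nm, first.wavelengths_nm, rtol=0, atol=1e-9
        ):
            raise GridMismatchError("replicate sets have different wavelength grids")
        if s.sample_ids != first.sample_ids:
            raise SpectraValidationError("replicate sets have different sample ids")
    mean = np.mean([s.values for s in stack], axis=0)
    return first.with_values(mean)


def to_absorbance(s: SpectraSet) -> SpectraSet:
    """Optional log10(1/R) transform; off by default in every pipeline."""
    if np.any(s.values <= 0):
        raise SpectraValidationError("non-positive reflectance: cannot take log(1/R)")
    return s.with_values(-np.log10(s.values))
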