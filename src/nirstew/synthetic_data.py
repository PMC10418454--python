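"""Synthetic dual-band meat spectra with realistic trait structure.

The generator emulates a 97-sample study of stewed-meat quality: five
reference traits (fat, protein, collagen, ash, Na; g/kg) with published
descriptive statistics and correlation structure, and two reflectance bands
(VNIR 650–949.8 nm at 0.35 nm pitch; NIR 960–1660 nm at 3.6 nm pitch) built
from Gaussian absorption bands of the organic components plus water.

Trait model
-----------
fat, protein and ash are truncated normals at the study's calibration-set
means/SDs, clipped to the printed ranges.  Na is an affine function of ash
plus noise (target r ≈ 0.77: both track the inorganic salt fraction), and
collagen is likewise tied to protein (target r ≈ 0.35).

Spectral model
--------------
A clean spectrum is linear in concentrations:
``A(λ) = Σ_k (c_k / 1000) · K_k(λ)`` where each component curve ``K_k`` is a
sum of Gaussian bands (third/second overtone and combination bands of O–H,
C–H, N–H).  Water concentration is the mass balance remainder
``total − fat − protein − collagen − ash`` (floor 0).  Ash and Na are
inorganic and contribute no absorption.  The observed spectrum adds
per-sample multiplicative scatter, additive offset, linear + quadratic
baseline drift and i.i.d. channel noise:

``obs = a·A + b + d₁·u + d₂·u² + ε``,  u = scaled wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .spectra_io import (
    ReferenceTable,
    SpectraSet,
    write_reference_csv,
    write_spectra_csv,
)


class ConfigError(ValueError):
    """Simulation configuration violates a feasibility constraint."""


@dataclass
class GaussianBand:
    center_nm: float
    width_nm: float
    amplitude: float  # absorption per unit (g/kg / 1000) of component

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ConfigError("band width must be positive")
        if self.amplitude < 0:
            raise ConfigError("band amplitude must be non-negative")


@dataclass
class ComponentBandLibrary:
    """Gaussian absorption bands per absorbing component."""

    bands: dict[str, list[GaussianBand]]

    def curve(self, component: str, grid: np.ndarray) -> np.ndarray:
        """Component absorption curve K(λ) on ``grid``; zero if non-absorbing."""
        out = np.zeros_like(grid, dtype=float)
        for b in self.bands.get(component, []):
            out += b.amplitude * np.exp(-((grid - b.center_nm) ** 2) / (2 * b.width_nm**2))
        return out


def default_band_library() -> ComponentBandLibrary:
    """Band assignments anchored at the features visible in meat spectra.

    Water: O–H third overtone near 771 nm, second overtone near 979 nm, and
    the strong combination band near 1423 nm.  Fat: C–H features near
    813/872 nm (weak third overtones) and the C–H second overtone near
    1220 nm.  Protein: N–H/C–H related bands near 910 nm and in the
    1020/1190/1500 nm region.  Collagen is protein-like: the same band
    pattern shifted a few nm at a quarter of the amplitude (it is a fibrous
    protein, so its signature is nearly — but not exactly — collinear with
    crude protein).
    """
    return ComponentBandLibrary(
        bands={
            "water": [
                GaussianBand(771.0, 25.0, 0.30),
                GaussianBand(979.0, 30.0, 1.00),
                GaussianBand(1423.0, 45.0, 1.20),
            ],
            "fat": [
                GaussianBand(813.0, 20.0, 0.20),
                GaussianBand(872.0, 20.0, 0.15),
                GaussianBand(1220.0, 25.0, 1.00),
            ],
            "protein": [
                GaussianBand(910.0, 25.0, 0.15),
                GaussianBand(1020.0, 25.0, 0.40),
                GaussianBand(1190.0, 30.0, 0.50),
                GaussianBand(1500.0, 40.0, 0.80),
            ],
            "collagen": [
                GaussianBand(915.0, 25.0, 0.0375),
                GaussianBand(1025.0, 25.0, 0.10),
                GaussianBand(1196.0, 30.0, 0.125),
                GaussianBand(1508.0, 40.0, 0.20),
            ],
        }
    )


@dataclass
class TraitDistribution:
    mean: float
    sd: float
    minimum: float
    maximum: float


def default_trait_distributions() -> dict[str, TraitDistribution]:
    """Calibration-set descriptive statistics of the emulated study (g/kg)."""
    return {
        "fat": TraitDistribution(51.2, 33.2, 16.5, 162.5),
        "protein": TraitDistribution(256.2, 56.4, 146.5, 425.5),
        "collagen": TraitDistribution(26.1, 18.6, 0.1, 104.0),
        "ash": TraitDistribution(28.0, 5.3, 12.0, 40.5),
        "Na": TraitDistribution(8.5, 2.4, 1.3, 16.2),
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic fixture.

    Defaults reproduce the emulated study: 97 samples, the published trait
    moments/ranges and correlations, and the two instrument grids after
    noise-band trimming.
    """

    n_samples: int = 97
    traits: dict[str, TraitDistribution] = field(default_factory=default_trait_distributions)
    ash_na_correlation: float = 0.77
    collagen_protein_correlation: float = 0.35
    scatter_mult_sd: float = 0.03
    scatter_add_sd: float = 0.01
    drift_linear_sd: float = 0.01
    drift_quad_sd: float = 0.01
    noise_sd: float = 0.02
    total_mass: float = 1000.0  # g/kg mass balance for the water remainder
    vnir_start: float = 650.0
    vnir_stop: float = 949.8
    vnir_pitch: float = 0.35
    nir_start: float = 960.0
    nir_stop: float = 1660.0
    nir_pitch: float = 3.6

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ConfigError("n_samples must be >= 10")
        for r in (self.ash_na_correlation, self.collagen_protein_correlation):
            if abs(r) > 0.999:
                raise ConfigError(f"infeasible correlation target {r}")

    def vnir_grid(self) -> np.ndarray:
        n = int(np.floor((self.vnir_stop - self.vnir_start) / self.vnir_pitch + 1e-9)) + 1
        return self.vnir_start + self.vnir_pitch * np.arange(n)

    def nir_grid(self) -> np.ndarray:
        n = int(np.floor((self.nir_stop - self.nir_start) / self.nir_pitch + 1e-9)) + 1
        return self.nir_start + self.nir_pitch * np.arange(n)


def _matched_truncnorm_params(dist: TraitDistribution) -> tuple[float, float]:
    """Location/scale whose *truncated* distribution has the target moments.

    Truncating a normal at asymmetric bounds shifts its mean and shrinks its
    SD, so drawing with the printed moments as loc/scale would not reproduce
    them.  Solve the two moment equations for (loc, scale) instead.
    """
    m, s = dist.mean, dist.sd

    def moments(x):
        loc, log_scale = x
        scale = np.exp(log_scale)
        a = (dist.minimum - loc) / scale
        b = (dist.maximum - loc) / scale
        mm, vv = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [mm - m, np.sqrt(vv) - s]

    from scipy.optimize import root

    sol = root(moments, x0=[m, np.log(s)], method="hybr")
    if not sol.success or max(abs(v) for v in moments(sol.x)) > 1e-6 * s:
        raise ConfigError(
            f"cannot match mean {m} / SD {s} on [{dist.minimum}, {dist.maximum}]"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _truncnorm(dist: TraitDistribution, size: int, rng: np.random.Generator) -> np.ndarray:
    """Bounded draw reproducing the printed mean/SD.

    Uses a moment-matched truncated normal; when the printed SD is too large
    for any truncated normal on the printed range (a right-skewed trait such
    as fat, whose SD is comparable to the mean-to-minimum distance), fall
    back to a moment-matched lognormal clipped to the range.
    """
    if dist.sd == 0:
        return np.full(size, dist.mean)
    try:
        loc, scale = _matched_truncnorm_params(dist)
    except ConfigError:
        cv2 = (dist.sd / dist.mean) ** 2
        sigma = np.sqrt(np.log1p(cv2))
        mu = np.log(dist.mean) - sigma**2 / 2
        draw = rng.lognormal(mu, sigma, size)
        return np.clip(draw, dist.minimum, dist.maximum)
    a = (dist.minimum - loc) / scale
    b = (dist.maximum - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _correlated_child(
    parent: np.ndarray,
    parent_dist: TraitDistribution,
    child_dist: TraitDistribution,
    r: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a trait as an affine function of ``parent`` plus noise, clipped.

    The slope r·(sd_child/sd_parent) targets a sample correlation of ``r``;
    clipping to the printed range attenuates it only marginally.
    """
    if child_dist.sd == 0:
        return np.full(parent.size, child_dist.mean)
    z = rng.standard_normal(parent.size)
    scale = child_dist.sd / parent_dist.sd if parent_dist.sd > 0 else 0.0
    child = (
        child_dist.mean
        + r * scale * (parent - parent_dist.mean)
        + child_dist.sd * np.sqrt(1.0 - r * r) * z
    )
    return np.clip(child, child_dist.minimum, child_dist.maximum)


def draw_reference_traits(cfg: SimConfig, seed: int | None) -> ReferenceTable:
    """Draw the five-trait reference table with the study's correlation structure."""
    rng = np.random.default_rng(seed)
    t = cfg.traits
    fat = _truncnorm(t["fat"], cfg.n_samples, rng)
    protein = _truncnorm(t["protein"], cfg.n_samples, rng)
    ash = _truncnorm(t["ash"], cfg.n_samples, rng)
    collagen = _correlated_child(
        protein, t["protein"], t["collagen"], cfg.collagen_protein_correlation, rng
    )
    na = _correlated_child(ash, t["ash"], t["Na"], cfg.ash_na_correlation, rng)
    ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    return ReferenceTable(
        ids,
        {"fat": fat, "protein": protein, "collagen": collagen, "ash": ash, "Na": na},
    )


def clean_signal(
    refs: ReferenceTable, lib: ComponentBandLibrary, cfg: SimConfig, grid: np.ndarray
) -> np.ndarray:
    """Noise-free spectra: linear in concentrations, water as mass remainder."""
    organics = refs.traits["fat"] + refs.traits["protein"] + refs.traits["collagen"]
    water = np.maximum(cfg.total_mass - organics - refs.traits["ash"], 0.0)
    conc = {
        "fat": refs.traits["fat"],
        "protein": refs.traits["protein"],
        "collagen": refs.traits["collagen"],
        "water": water,
    }
    A = np.zeros((refs.n_samples, grid.size))
    for comp, c in conc.items():
        A += np.outer(c / cfg.total_mass, lib.curve(comp, grid))
    return A


def _corrupt(
    A: np.ndarray, grid: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    n = A.shape[0]
    a = rng.normal(1.0, cfg.scatter_mult_sd, n)
    b = rng.normal(0.0, cfg.scatter_add_sd, n)
    d1 = rng.normal(0.0, cfg.drift_linear_sd, n)
    d2 = rng.normal(0.0, cfg.drift_quad_sd, n)
    u = (grid - grid.mean()) / (np.ptp(grid) / 2)
    eps = rng.normal(0.0, cfg.noise_sd, A.shape)
    return (
        a[:, None] * A
        + b[:, None]
        + d1[:, None] * u[None, :]
        + d2[:, None] * u[None, :] ** 2
        + eps
    )


def render_spectra(
    refs: ReferenceTable,
    lib: ComponentBandLibrary,
    cfg: SimConfig,
    seed: int | None,
) -> tuple[SpectraSet, SpectraSet]:
    """Render the (VNIR, NIR) spectra sets for a reference table.

    The two instruments get independent scatter/drift/noise draws.
    """
    rng = np.random.default_rng(seed)
    out = []
    for label, grid in (("VNIR", cfg.vnir_grid()), ("NIR", cfg.nir_grid())):
        A = clean_signal(refs, lib, cfg, grid)
        obs = _corrupt(A, grid, cfg, rng)
        out.append(SpectraSet(grid, obs, label, list(refs.sample_ids)))
    return out[0], out[1]


def make_fixture(
    cfg: SimConfig,
    seed: int | None,
    out_dir: str | Path,
    lib: ComponentBandLibrary | None = None,
) -> dict[str, Path]:
    """Write ``vnir.csv``, ``nir.csv`` and ``reference.csv``; deterministic per seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lib = lib or default_band_library()
    refs = draw_reference_traits(cfg, seed)
    render_seed = None if seed is None else seed + 1
    vnir, nir = render_spectra(refs, lib, cfg, render_seed)
    paths = {
        "vnir": out_dir / "vnir.csv",
        "nir": out_dir / "nir.csv",
        "reference": out_dir / "reference.csv",
    }
    write_spectra_csv(vnir, paths["vnir"])
    write_spectra_csv(nir, paths["nir"])
    write_reference_csv(refs, paths["reference"])
    return paths


def make_planted_dataset(
    n: int, p: int, n_informative: int, snr: float, seed: int | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regression design with known informative columns, for selector benchmarks.

    ``X`` is i.i.d. standard normal; ``y`` is a ±1-weighted sum of
    ``n_informative`` evenly spread columns plus Gaussian noise at the given
    signal-to-noise (variance) ratio.  Returns ``(X, y, informative_idx)``.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    idx = np.linspace(0, p - 1, n_informative, dtype=int)
    coef = np.where(np.arange(n_informative) % 2 == 0, 1.0, -1.0)
    signal = X[:, idx] @ coef
    noise_sd = np.sqrt(np.var(signal) / snr) if snr > 0 else 0.0
    y = signal + rng.normal(0.0, noise_sd, n)
    return X, y, idx
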