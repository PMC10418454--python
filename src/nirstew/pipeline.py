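"""End-to-end dual-band calibration experiment.

The experiment mirrors a standard chemometric workflow:

1. obtain dual-band spectra and reference chemistry (simulated or from CSV),
2. trim the high-noise band edges,
3. split samples into calibration and prediction sets,
4. screen every (band, preprocessing, trait) cell with full-spectrum PLSR,
   choosing LVs by LOOCV and the optimal cell by minimum RMSECV,
5. gate traits on full-spectrum RPD >= 1.5,
6. select wavelengths for the surviving traits by regression-coefficient
   extrema (RC) and random frog (RF),
7. rebuild multispectral PLSR models on the selected wavelengths,
8. write descriptive, correlation, screening, selection and multispectral
   report tables as CSV.

The prediction set influences nothing upstream of final metric evaluation:
LV choice, preprocessing choice and wavelength selection all see calibration
rows only.  (The RPD gate reads prediction-set metrics, as the emulated
study's own trait-retention decision did.)
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data
from .evaluation import (
    EvaluationReport,
    SplitSpec,
    descriptive_stats,
    pearson_matrix,
    random_split,
    regression_metrics,
    rpd,
    rpd_label,
)
from .plsr import PLSRModel, RankDeficiencyError, fit_plsr, loocv_select_lv, predict
from .preprocessing import PREPROC_NAMES, PreprocSpec, apply_preprocessing
from .spectra_io import (
    NIR_KEEP,
    TRAITS,
    VNIR_KEEP,
    BandSpec,
    ReferenceTable,
    SpectraSet,
    read_reference_csv,
    read_spectra_csv,
    trim_noise_bands,
)
from .wavelength_selection import RFParams, SelectionResult, random_frog, select_by_rc

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 7,
    "simulate": True,
    "data_dir": None,
    "n_samples": 97,
    "n_calibration": 70,
    "a_max": 15,
    "preprocs": list(PREPROC_NAMES),
    "rpd_gate": 1.5,
    "rf": {},                      # overrides for RFParams fields
    "n_sel_rc": {"fat": 7, "protein": 8},
    "n_sel_rc_default": 8,
    "n_sel_rf": 10,
}


@dataclass
class ScreeningGrid:
    """Axes of the preprocessing screen; one split shared by every cell."""

    band_labels: Sequence[str]
    preproc_names: Sequence[str]
    traits: Sequence[str]
    split: SplitSpec
    a_max: int = 15

    def __post_init__(self) -> None:
        if not (self.band_labels and self.preproc_names and self.traits):
            raise ValueError("screening grid axes must be non-empty")


@dataclass
class CellResult:
    """One screening cell: its report plus the fitted artefacts."""

    report: EvaluationReport
    model: PLSRModel
    grid_nm: np.ndarray


@dataclass
class RunResult:
    """Everything a caller needs from a full analysis run."""

    reports: list[EvaluationReport]
    optimal: dict[tuple[str, str], CellResult]       # (trait, band) -> best cell
    best_band: dict[str, str]                        # trait -> band of overall best cell
    gated_traits: list[str]
    selections: dict[tuple[str, str], SelectionResult]   # (trait, method)
    multispectral: dict[tuple[str, str], EvaluationReport]
    tables: dict[str, Path]
    split: SplitSpec


def _rows(s: SpectraSet, ids: Sequence[str]) -> np.ndarray:
    pos = {sid: i for i, sid in enumerate(s.sample_ids)}
    return s.values[[pos[i] for i in ids]]


def evaluate_cell(
    spectra: SpectraSet,
    refs: ReferenceTable,
    trait: str,
    split: SplitSpec,
    a_max: int,
    preprocessing: str,
) -> CellResult:
    """Fit + evaluate one (preprocessed band, trait) cell.

    LVs are chosen by LOOCV on the calibration rows; the prediction set is
    used for R_p/RMSEP/RPD only.
    """
    y = refs.to_frame()[trait]
    X_cal = _rows(spectra, split.calibration_ids)
    y_cal = y.loc[split.calibration_ids].to_numpy()
    X_pred = _rows(spectra, split.prediction_ids)
    y_pred_ref = y.loc[split.prediction_ids].to_numpy()

    cv = loocv_select_lv(X_cal, y_cal, a_max)
    model = fit_plsr(X_cal, y_cal, cv.optimal_lv)
    r_c, rmsec = regression_metrics(y_cal, predict(model, X_cal))
    yhat = predict(model, X_pred)
    r_p, rmsep = regression_metrics(y_pred_ref, yhat)
    sd_pred = float(np.std(y_pred_ref, ddof=1))
    report = EvaluationReport(
        trait=trait,
        band=spectra.band_label,
        preprocessing=preprocessing,
        n_lv=cv.optimal_lv,
        r_c=r_c,
        rmsec=rmsec,
        r_cv=cv.r_cv,
        rmsecv=float(cv.rmsecv_by_lv[cv.optimal_lv - 1]),
        r_p=r_p,
        rmsep=rmsep,
        rpd=rpd(sd_pred, rmsep),
    )
    return CellResult(report, model, spectra.wavelengths_nm)


def screen_preprocessings(
    spectra_by_band: dict[str, SpectraSet],
    refs: ReferenceTable,
    grid: ScreeningGrid,
) -> tuple[list[EvaluationReport], dict[tuple[str, str], CellResult]]:
    """Evaluate every (band, preprocessing, trait) cell.

    Returns all reports plus, per (trait, band), the cell minimising RMSECV.
    Cell failures (rank exhaustion) are logged and skipped, not fatal.
    """
    reports: list[EvaluationReport] = []
    optimal: dict[tuple[str, str], CellResult] = {}
    for band in grid.band_labels:
        raw = spectra_by_band[band]
        for preproc in grid.preproc_names:
            processed = apply_preprocessing(raw, PreprocSpec(name=preproc))
            for trait in grid.traits:
                try:
                    cell = evaluate_cell(
                        processed, refs, trait, grid.split, grid.a_max, preproc
                    )
                except (RankDeficiencyError, ValueError) as exc:
                    logger.warning("cell (%s, %s, %s) failed: %s", band, preproc, trait, exc)
                    continue
                reports.append(cell.report)
                key = (trait, band)
                if key not in optimal or cell.report.rmsecv < optimal[key].report.rmsecv:
                    optimal[key] = cell
    return reports, optimal


def map_to_grid(grid_nm: np.ndarray, requested_nm: Sequence[float]) -> np.ndarray:
    """Nearest-grid-point indices for requested wavelengths.

    Tolerance is half the local grid pitch; anything farther is an error
    (the request belongs to a different instrument grid).  Duplicates after
    mapping collapse to unique columns.
    """
    grid_nm = np.asarray(grid_nm, dtype=float)
    pitch = np.diff(grid_nm)
    idx, offenders = [], []
    for nm in requested_nm:
        i = int(np.clip(np.searchsorted(grid_nm, nm), 1, grid_nm.size - 1))
        i = i if abs(grid_nm[i] - nm) < abs(grid_nm[i - 1] - nm) else i - 1
        local = pitch[min(max(i - 1, 0), pitch.size - 1)]
        if abs(grid_nm[i] - nm) > local / 2 + 1e-9:
            offenders.append(nm)
        idx.append(i)
    if offenders:
        raise ValueError(f"wavelengths not on the grid (beyond half-pitch): {offenders}")
    return np.unique(idx)


def build_multispectral_model(
    spectra: SpectraSet,
    refs: ReferenceTable,
    trait: str,
    selection: SelectionResult | Sequence[float],
    split: SplitSpec,
    a_max: int = 15,
    preprocessing: str = "",
) -> EvaluationReport:
    """Refit PLSR on selected wavelengths only and evaluate the reduced model."""
    nm = selection.selected_nm if isinstance(selection, SelectionResult) else np.asarray(selection, float)
    if len(nm) == 0:
        raise ValueError("empty wavelength selection")
    cols = map_to_grid(spectra.wavelengths_nm, nm)
    sub = SpectraSet(
        spectra.wavelengths_nm[cols],
        spectra.values[:, cols],
        spectra.band_label,
        list(spectra.sample_ids),
    )
    cell = evaluate_cell(sub, refs, trait, split, min(a_max, cols.size), preprocessing)
    return cell.report


def reports_to_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in reports])
    num = df.select_dtypes("float").columns
    df[num] = df[num].round(3)
    return df


def _load_config(config: dict[str, Any] | str | Path | None) -> dict[str, Any]:
    cfg = dict(DEFAULT_CONFIG)
    if config is None:
        return cfg
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config)
    return cfg


def load_or_simulate(cfg: dict[str, Any], work_dir: Path) -> tuple[dict[str, SpectraSet], ReferenceTable]:
    """Either read the three CSVs from ``data_dir`` or simulate a fixture."""
    if cfg["simulate"]:
        sim = synthetic_data.SimConfig(n_samples=cfg["n_samples"])
        data_dir = work_dir / "data"
        synthetic_data.make_fixture(sim, cfg["seed"], data_dir)
    else:
        data_dir = Path(cfg["data_dir"])
    spectra = {
        "VNIR": read_spectra_csv(data_dir / "vnir.csv", "VNIR"),
        "NIR": read_spectra_csv(data_dir / "nir.csv", "NIR"),
    }
    refs = read_reference_csv(data_dir / "reference.csv")
    return spectra, refs


def run_full_analysis(
    config: dict[str, Any] | str | Path | None,
    out_dir: str | Path,
    scratch_dir: str | Path | None = None,
) -> RunResult:
    """Run the whole experiment and write the five report tables.

    ``out_dir`` receives the small CSV reports; bulky simulated spectra go to
    ``scratch_dir`` (defaults to ``out_dir/scratch``).  Fully deterministic
    given the config seed.
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scratch = Path(scratch_dir) if scratch_dir is not None else out_dir / "scratch"
    seed = int(cfg["seed"])

    raw_spectra, refs = load_or_simulate(cfg, scratch)
    spectra = {
        "VNIR": trim_noise_bands(raw_spectra["VNIR"], BandSpec([VNIR_KEEP], "VNIR-keep")),
        "NIR": trim_noise_bands(raw_spectra["NIR"], BandSpec([NIR_KEEP], "NIR-keep")),
    }
    split = random_split(refs.sample_ids, cfg["n_calibration"], seed + 100)

    # Table 1: descriptive statistics per subset
    rows = []
    for subset, ids in (("calibration", split.calibration_ids), ("prediction", split.prediction_ids)):
        sub = refs.subset(ids)
        for trait in TRAITS:
            d = descriptive_stats(sub.traits[trait])
            rows.append(
                {
                    "trait": trait,
                    "subset": subset,
                    "n": len(ids),
                    "mean": round(d.mean, 1),
                    "sd": round(d.sd, 1),
                    "min": round(d.minimum, 1),
                    "max": round(d.maximum, 1),
                    "cv_percent": round(d.cv_percent, 1),
                }
            )
    table1 = pd.DataFrame(rows)

    # Table 2: trait Pearson correlations with significance flags
    r_mat, flag_mat = pearson_matrix(refs)
    table2 = r_mat.round(3).astype(str) + " " + flag_mat
    table2 = table2.apply(lambda col: col.str.strip())

    # Table 3: full-spectrum screening
    grid = ScreeningGrid(
        band_labels=("VNIR", "NIR"),
        preproc_names=cfg["preprocs"],
        traits=TRAITS,
        split=split,
        a_max=cfg["a_max"],
    )
    reports, optimal = screen_preprocessings(spectra, refs, grid)
    table3 = reports_to_frame(reports)
    opt_keys = {
        (c.report.trait, c.report.band, c.report.preprocessing) for c in optimal.values()
    }
    table3["optimal"] = [
        (t, b, p) in opt_keys
        for t, b, p in zip(table3["trait"], table3["band"], table3["preprocessing"])
    ]

    # Best band per trait (min RMSECV across bands), then the RPD gate
    best_band: dict[str, str] = {}
    for trait in TRAITS:
        cands = {b: optimal[(trait, b)] for b in grid.band_labels if (trait, b) in optimal}
        if cands:
            best_band[trait] = min(cands, key=lambda b: cands[b].report.rmsecv)
    gated = [
        t
        for t in TRAITS
        if t in best_band and optimal[(t, best_band[t])].report.rpd >= cfg["rpd_gate"]
    ]

    # Wavelength selection on the gated traits (calibration rows only)
    rf_params = RFParams(**cfg["rf"])
    selections: dict[tuple[str, str], SelectionResult] = {}
    sel_rows = []
    for k, trait in enumerate(gated):
        cell = optimal[(trait, best_band[trait])]
        processed = apply_preprocessing(
            spectra[best_band[trait]], PreprocSpec(name=cell.report.preprocessing)
        )
        X_cal = _rows(processed, split.calibration_ids)
        y_cal = refs.to_frame()[trait].loc[split.calibration_ids].to_numpy()
        n_rc = cfg["n_sel_rc"].get(trait, cfg["n_sel_rc_default"])
        selections[(trait, "RC")] = select_by_rc(cell.model, cell.grid_nm, n_rc)
        selections[(trait, "RF")] = random_frog(
            X_cal,
            y_cal,
            cell.grid_nm,
            rf_params,
            n_sel=cfg["n_sel_rf"],
            seed=seed + 1000 + k,
        )
        for method in ("RC", "RF"):
            s = selections[(trait, method)]
            for rank, nm in enumerate(
                sorted(
                    s.selected_nm,
                    key=lambda w: -s.importance[np.searchsorted(s.grid_nm, w)],
                ),
                start=1,
            ):
                sel_rows.append(
                    {
                        "trait": trait,
                        "method": method,
                        "rank": rank,
                        "wavelength_nm": round(float(nm), 2),
                        "importance": round(
                            float(s.importance[np.searchsorted(s.grid_nm, nm)]), 4
                        ),
                    }
                )
    table4 = pd.DataFrame(
        sel_rows, columns=["trait", "method", "rank", "wavelength_nm", "importance"]
    )

    # Table 5: multispectral rebuilds
    multispectral: dict[tuple[str, str], EvaluationReport] = {}
    for trait in gated:
        cell = optimal[(trait, best_band[trait])]
        processed = apply_preprocessing(
            spectra[best_band[trait]], PreprocSpec(name=cell.report.preprocessing)
        )
        for method in ("RC", "RF"):
            rep = build_multispectral_model(
                processed,
                refs,
                trait,
                selections[(trait, method)],
                split,
                a_max=cfg["a_max"],
                preprocessing=cell.report.preprocessing,
            )
            multispectral[(trait, method)] = rep
    table5 = reports_to_frame(list(multispectral.values())) if multispectral else pd.DataFrame()
    if not table5.empty:
        table5.insert(1, "method", [k[1] for k in multispectral])

    tables = {
        "descriptives": out_dir / "table1_descriptives.csv",
        "correlations": out_dir / "table2_correlations.csv",
        "screening": out_dir / "table3_screening.csv",
        "selection": out_dir / "table4_selected_wavelengths.csv",
        "multispectral": out_dir / "table5_multispectral.csv",
    }
    table1.to_csv(tables["descriptives"], index=False)
    table2.to_csv(tables["correlations"])
    table3.to_csv(tables["screening"], index=False)
    table4.to_csv(tables["selection"], index=False)
    table5.to_csv(tables["multispectral"], index=False)
    manifest = {
        "seed": seed,
        "best_band": best_band,
        "gated_traits": gated,
        "rpd_labels": {
            t: rpd_label(optimal[(t, best_band[t])].report.rpd) for t in best_band
        },
        "tables": {k: str(v) for k, v in tables.items()},
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    tables["manifest"] = out_dir / "run_manifest.json"

    return RunResult(
        reports=reports,
        optimal=optimal,
        best_band=best_band,
        gated_traits=gated,
        selections=selections,
        multispectral=multispectral,
        tables=tables,
        split=split,
    )
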