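#!/usr/bin/env python
"""Screen every (band, preprocessing, trait) cell with full-spectrum PLSR.

Reads the fixture from scratch/data (run 01_simulate.py first, or it is
regenerated here), trims the noise bands, makes the 70/27 split, and writes
the screening table plus the per-trait optimal models to results/.  Findings
are printed: which band and preprocessing wins per trait, and which traits
pass the RPD >= 1.5 gate.
"""

import json
from pathlib import Path

from nirstew.evaluation import random_split
from nirstew.pipeline import ScreeningGrid, reports_to_frame, screen_preprocessings
from nirstew.preprocessing import PREPROC_NAMES
from nirstew.spectra_io import (
    NIR_KEEP, TRAITS, VNIR_KEEP, BandSpec,
    read_reference_csv, read_spectra_csv, trim_noise_bands,
)
from nirstew.synthetic_data import SimConfig, make_fixture

ROOT = Path(__file__).resolve().parents[1]
SEED = 7
RPD_GATE = 1.5


def load_data():
    data_dir = ROOT / "scratch" / "data"
    if not (data_dir / "reference.csv").exists():
        make_fixture(SimConfig(), SEED, data_dir)
    spectra = {
        "VNIR": trim_noise_bands(read_spectra_csv(data_dir / "vnir.csv", "VNIR"),
                                 BandSpec([VNIR_KEEP], "VNIR-keep")),
        "NIR": trim_noise_bands(read_spectra_csv(data_dir / "nir.csv", "NIR"),
                                BandSpec([NIR_KEEP], "NIR-keep")),
    }
    return spectra, read_reference_csv(data_dir / "reference.csv")


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    spectra, refs = load_data()
    split = random_split(refs.sample_ids, 70, SEED + 100)

    grid = ScreeningGrid(("VNIR", "NIR"), PREPROC_NAMES, TRAITS, split, a_max=15)
    reports, optimal = screen_preprocessings(spectra, refs, grid)
    frame = reports_to_frame(reports)
    frame.to_csv(results / "screening_full_spectrum.csv", index=False)

    state = {"seed": SEED, "split_seed": SEED + 100, "optimal": {}}
    print(f"{len(reports)} cells screened; optimal per trait (min RMSECV across bands):")
    for trait in TRAITS:
        cands = {b: optimal[(trait, b)] for b in ("VNIR", "NIR") if (trait, b) in optimal}
        band = min(cands, key=lambda b: cands[b].report.rmsecv)
        rep = cands[band].report
        gate = "passes" if rep.rpd >= RPD_GATE else "fails"
        print(f"  {trait:9s} {band:4s} {rep.preprocessing:5s} LV={rep.n_lv:2d} "
              f"Rcv={rep.r_cv:.3f} Rp={rep.r_p:.3f} RPD={rep.rpd:.3f}  {gate} gate")
        state["optimal"][trait] = {
            "band": band, "preprocessing": rep.preprocessing,
            "n_lv": rep.n_lv, "rpd": round(rep.rpd, 3),
            "passes_gate": bool(rep.rpd >= RPD_GATE),
        }
    with open(results / "screening_state.json", "w") as fh:
        json.dump(state, fh, indent=2)


if __name__ == "__main__":
    main()
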