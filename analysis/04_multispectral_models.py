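#!/usr/bin/env python
"""Rebuild PLSR models on the selected wavelengths and compare to full spectra.

Reads the selections from 03_select_wavelengths.py, refits reduced models
(LVs re-chosen by LOOCV), and reports whether each simplified model stays
within 0.1 R_p of its full-spectrum parent.  Writes the comparison table to
results/.
"""

import importlib.util
import json
from pathlib import Path

import pandas as pd

from nirstew.evaluation import random_split
from nirstew.pipeline import build_multispectral_model, evaluate_cell
from nirstew.preprocessing import PreprocSpec, apply_preprocessing

ROOT = Path(__file__).resolve().parents[1]
_spec = importlib.util.spec_from_file_location("screen", ROOT / "analysis" / "02_screen_preprocessing.py")
screen = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(screen)


def main() -> None:
    results = ROOT / "results"
    with open(results / "screening_state.json") as fh:
        state = json.load(fh)
    selections = pd.read_csv(results / "selected_wavelengths.csv")
    spectra, refs = screen.load_data()
    split = random_split(refs.sample_ids, 70, state["split_seed"])

    rows = []
    for (trait, method), group in selections.groupby(["trait", "method"]):
        info = state["optimal"][trait]
        processed = apply_preprocessing(
            spectra[info["band"]], PreprocSpec(name=info["preprocessing"])
        )
        full = evaluate_cell(processed, refs, trait, split, 15, info["preprocessing"]).report
        reduced = build_multispectral_model(
            processed, refs, trait, group["wavelength_nm"].to_numpy(),
            split, a_max=15, preprocessing=info["preprocessing"],
        )
        within = reduced.r_p > full.r_p - 0.1
        print(f"{trait} {method}-PLSR ({len(group)} nm): Rp={reduced.r_p:.3f} "
              f"RPD={reduced.rpd:.3f} vs full Rp={full.r_p:.3f} -> "
              f"{'within' if within else 'beyond'} 0.1 Rp of full spectrum")
        rows.append({"trait": trait, "method": method, "n_wavelengths": len(group),
                     "n_lv": reduced.n_lv,
                     "r_c": round(reduced.r_c, 3), "rmsec": round(reduced.rmsec, 3),
                     "r_cv": round(reduced.r_cv, 3), "rmsecv": round(reduced.rmsecv, 3),
                     "r_p": round(reduced.r_p, 3), "rmsep": round(reduced.rmsep, 3),
                     "rpd": round(reduced.rpd, 3),
                     "full_spectrum_r_p": round(full.r_p, 3)})
    pd.DataFrame(rows).to_csv(results / "multispectral_models.csv", index=False)
    print("wrote results/multispectral_models.csv")


if __name__ == "__main__":
    main()
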