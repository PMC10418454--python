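#!/usr/bin/env python
"""Select informative wavelengths for the traits that passed the RPD gate.

Uses the optimal band/preprocessing recorded by 02_screen_preprocessing.py,
refits the calibration model, and runs both selectors: regression-coefficient
extrema (7 wavelengths for fat, 8 for protein) and random frog (N = 1000,
10 wavelengths).  Writes the selected wavelengths to results/.
"""

import importlib.util
import json
from pathlib import Path

import numpy as np
import pandas as pd

from nirstew.evaluation import random_split
from nirstew.plsr import fit_plsr, loocv_select_lv
from nirstew.preprocessing import PreprocSpec, apply_preprocessing
from nirstew.wavelength_selection import RFParams, random_frog, select_by_rc

ROOT = Path(__file__).resolve().parents[1]
_spec = importlib.util.spec_from_file_location("screen", ROOT / "analysis" / "02_screen_preprocessing.py")
screen = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(screen)

N_SEL_RC = {"fat": 7, "protein": 8}


def main() -> None:
    results = ROOT / "results"
    with open(results / "screening_state.json") as fh:
        state = json.load(fh)
    spectra, refs = screen.load_data()
    split = random_split(refs.sample_ids, 70, state["split_seed"])

    rows = []
    for k, (trait, info) in enumerate(sorted(state["optimal"].items())):
        if not info["passes_gate"]:
            continue
        processed = apply_preprocessing(
            spectra[info["band"]], PreprocSpec(name=info["preprocessing"])
        )
        pos = {s: i for i, s in enumerate(processed.sample_ids)}
        X = processed.values[[pos[i] for i in split.calibration_ids]]
        y = refs.to_frame()[trait].loc[split.calibration_ids].to_numpy()

        cv = loocv_select_lv(X, y, 15)
        model = fit_plsr(X, y, cv.optimal_lv)
        rc = select_by_rc(model, processed.wavelengths_nm, N_SEL_RC.get(trait, 8))
        rf = random_frog(X, y, processed.wavelengths_nm, RFParams(),
                         n_sel=10, seed=state["seed"] + 1000 + k)
        for sel in (rc, rf):
            print(f"{trait} {sel.method}: {np.round(sel.selected_nm, 1).tolist()}")
            for nm in sel.selected_nm:
                i = int(np.searchsorted(sel.grid_nm, nm))
                rows.append({"trait": trait, "method": sel.method,
                             "wavelength_nm": round(float(nm), 2),
                             "importance": round(float(sel.importance[i]), 4)})
    pd.DataFrame(rows).to_csv(results / "selected_wavelengths.csv", index=False)
    print(f"wrote {len(rows)} selected wavelengths -> results/selected_wavelengths.csv")


if __name__ == "__main__":
    main()
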