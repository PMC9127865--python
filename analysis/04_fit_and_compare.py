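"""Fit the main model space to the synthetic cohorts and compare models.

MAP-fits each candidate family to every subject of the opposing-learning
cohorts from 01_simulate_cohorts.py, runs random-effects Bayesian model
selection on the BICs (xp/pxp), and scores transfer-phase prediction NLL
(all pairs and the critical equal-value A1A2 pair).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from contextrl.fitting import map_fit, transfer_nll
from contextrl.model_selection import random_effects_bms
from contextrl.synthetic_data import read_cohort

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"

SPACES = {"partial": ["SQL", "RPA", "Hyb", "OL1", "OL2"],
          "complete": ["SQL", "RPA", "Dif", "Hyb", "OL1", "OL2"]}

for regime, models in SPACES.items():
    path = OUT / f"cohort_ol1_{regime}.csv"
    if not path.exists():
        raise SystemExit(f"{path} missing - run 01_simulate_cohorts.py first")
    cohort = read_cohort(path)
    rows = []
    for ds in cohort:
        for key in models:
            fr = map_fit(key, ds, n_restarts=5, seed=17)
            tot, a1a2 = transfer_nll(key, fr, ds)
            rows.append({"subject": ds.subject_id, "model": key,
                         "nll": fr.learning_nll, "bic": fr.bic, "aic": fr.aic,
                         "transfer_all": tot, "transfer_a1a2": a1a2})
    fits = pd.DataFrame(rows)
    fits.to_csv(OUT / f"fits_{regime}.csv", index=False)

    bic = fits.pivot(index="subject", columns="model", values="bic")[models]
    bms = random_effects_bms(-0.5 * bic.to_numpy(), models=models, seed=1)
    comp = pd.DataFrame({"model": models, "xp": bms.xp, "pxp": bms.pxp,
                         "freq": bms.expected_frequencies})
    comp.to_csv(OUT / f"model_comparison_{regime}.csv", index=False)
    trans = fits.groupby("model")[["transfer_all", "transfer_a1a2"]] \
        .agg(["mean", "sem"]).round(2)
    print(f"\n=== {regime} (generator: OL1) ===")
    print(comp.round(4).to_string(index=False))
    print(trans.to_string())
    winner = comp.loc[comp["xp"].idxmax(), "model"]
    print(f"BMS winner: {winner} (xp {comp['xp'].max():.3f})")
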