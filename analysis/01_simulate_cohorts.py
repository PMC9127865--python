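"""Simulate study-sized synthetic cohorts of opposing-learning agents.

Generates 35 partial-feedback and 42 complete-feedback subjects (the study's
cohort sizes) with parameters sampled from the fitted-parameter summaries,
playing the full three-phase task, and writes them as cohort CSVs.
"""

from pathlib import Path

from contextrl.synthetic_data import simulate_cohort, write_cohort
from contextrl.task_env import default_config

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

for regime, n in (("partial", 35), ("complete", 42)):
    cohort = simulate_cohort("OL1", None, n, default_config(regime), seed=11,
                             skip_excluded=True)
    path = OUT / f"cohort_ol1_{regime}.csv"
    write_cohort(cohort, path)
    lengths = [d.meta["n_learning"] for d in cohort]
    print(f"{regime}: {n} subjects, learning-phase lengths "
          f"{min(lengths)}-{max(lengths)} trials -> {path.name}")
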