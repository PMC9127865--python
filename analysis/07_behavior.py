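"""Behavioral signatures of the synthetic cohorts.

Learning/transfer accuracy, the transfer bias (preference for A2 over the
equal-valued A1) with its exact binomial test, and the confound features
(choice-frequency difference, extreme-reward sums) with the logistic checks.
"""

from pathlib import Path

import numpy as np

from contextrl.behavior_stats import (cohort_summary, logistic_confound_test,
                                      transfer_bias_test)
from contextrl.synthetic_data import read_cohort

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"

for regime in ("partial", "complete"):
    path = OUT / f"cohort_ol1_{regime}.csv"
    if not path.exists():
        raise SystemExit(f"{path} missing - run 01_simulate_cohorts.py first")
    cohort = read_cohort(path)
    summary = cohort_summary(cohort)
    summary.to_csv(OUT / f"behavior_summary_{regime}.csv", index=False)
    bias = transfer_bias_test(cohort)
    print(f"=== {regime} ===")
    print(f"learning accuracy {summary['learning_accuracy'].mean():.3f} "
          f"± {summary['learning_accuracy'].std():.3f}; "
          f"transfer accuracy {summary['transfer_accuracy'].mean():.3f}")
    print(f"first-iteration A2 ratio {bias['ratio']:.3f} "
          f"({bias['k']}/{bias['n']}), one-sided binomial p = {bias['p_value']:.4f}")
    # does choice frequency explain the A2 preference?
    y = summary["first_a2_over_a1"].astype(float)
    if y.nunique() > 1:
        table = logistic_confound_test(y, summary["freq_diff_a2_a1"])
        print("logistic check (A2 preference ~ choice-frequency difference):")
        print(table.round(4).to_string())
    print()
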