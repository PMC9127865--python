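"""Anti-correlation of paired option values under opposing learning.

Sweeps the unchosen/chosen learning-rate ratio and measures the Pearson
correlation between the two learned values of one context; the law
corr(Q1, Q2) ~ -alpha2/alpha1 should hold across the grid.
"""

from pathlib import Path

import pandas as pd

from contextrl.synthetic_data import qvalue_correlation_experiment

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for ratio in (0.0, 0.25, 0.5, 0.75, 1.0):
    res = qvalue_correlation_experiment(alpha1=0.2, alpha2=ratio * 0.2,
                                        beta=0.1, pair_means=(7.0, 5.0),
                                        n_trials=1000, n_runs=20, seed=42)
    rows.append({"ratio": ratio, "predicted": -ratio,
                 "mean_corr": res["mean"], "se": res["se"]})
    print(f"alpha2/alpha1 = {ratio:4.2f}: corr = {res['mean']:+.3f} "
          f"(SE {res['se']:.3f}), law predicts {-ratio:+.2f}")

pd.DataFrame(rows).to_csv(OUT / "value_correlation.csv", index=False)
print(f"-> {OUT / 'value_correlation.csv'}")
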