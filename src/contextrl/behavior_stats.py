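"""Cohort-level behavioral summaries: learning curves, the transfer bias
(preference of A2 over the equal-valued A1) with its exact binomial test,
and the confound features used to rule out frequency/extreme-reward accounts
of that bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import BehavioralDataset
from .task_env import LEARNING, TRANSFER

__all__ = ["performance", "transfer_bias_test", "confound_features",
           "logistic_confound_test", "cohort_summary"]


def _advantageous(config_means: dict[str, float] | None, ds: BehavioralDataset):
    """Map context -> higher-mean stimulus. Synthetic datasets default to the
    study's means; real data must supply the mapping."""
    means = config_means or {"A1": 64.0, "B": 54.0, "A2": 64.0, "C": 44.0}

    def best(a: str, b: str) -> str:
        return a if means[a] >= means[b] else b
    return means, best


def performance(dataset: BehavioralDataset, phase: str = LEARNING,
                config_means: dict[str, float] | None = None,
                bin_width: int = 10):
    """Fraction of answered trials choosing the higher-mean option, plus
    per-context curves binned at ``bin_width`` trials."""
    df = dataset.phase(phase)
    answered = df[df["choice"].notna() & (df["choice"] != "")]
    if answered.empty:
        raise ValueError(f"no answered trials in phase {phase!r}")
    means, best = _advantageous(config_means, dataset)
    # pairs with equal expected reward (A1 vs A2) have no advantageous option
    unequal = answered[
        [means[r.stim_left] != means[r.stim_right]
         for r in answered.itertuples(index=False)]
    ]
    if unequal.empty:
        raise ValueError(f"no unequal-mean trials in phase {phase!r}")
    answered = unequal
    correct = np.array([
        row.choice == best(row.stim_left, row.stim_right)
        for row in answered.itertuples(index=False)
    ])
    curves = {}
    if phase == LEARNING:
        for ctx, sub in answered.assign(correct=correct).groupby("context"):
            vals = sub["correct"].to_numpy(float)
            n_bins = int(np.ceil(len(vals) / bin_width))
            curves[ctx] = np.array([
                vals[i * bin_width:(i + 1) * bin_width].mean()
                for i in range(n_bins)
            ])
    return float(correct.mean()), curves


def _first_and_rate_a2(ds: BehavioralDataset):
    """First-iteration A2-over-A1 indicator and the all-iteration A2 rate."""
    tr = ds.phase(TRANSFER)
    mask = tr.apply(lambda r: {r["stim_left"], r["stim_right"]} == {"A1", "A2"}, axis=1)
    pair = tr[mask & tr["choice"].notna()]
    if pair.empty:
        return None
    chose_a2 = (pair["choice"] == "A2").to_numpy()
    return bool(chose_a2[0]), float(chose_a2.mean())


def transfer_bias_test(cohort: list[BehavioralDataset], alternative: str = "greater"):
    """Fraction of subjects choosing A2 on their first (A1, A2) transfer trial
    and the exact binomial tail against chance (one-sided toward A2 by
    default); also returns the per-subject all-iteration A2 rates."""
    firsts, rates, excluded = [], [], []
    for ds in cohort:
        out = _first_and_rate_a2(ds)
        if out is None:
            excluded.append(ds.subject_id)
            continue
        firsts.append(out[0])
        rates.append(out[1])
    if not firsts:
        raise ValueError("no subject has an answered (A1, A2) transfer trial")
    k, n = int(np.sum(firsts)), len(firsts)
    test = stats.binomtest(k, n, p=0.5, alternative=alternative)
    return {
        "ratio": k / n, "k": k, "n": n, "p_value": float(test.pvalue),
        "all_iteration_rates": np.asarray(rates), "excluded_subjects": excluded,
    }


def confound_features(dataset: BehavioralDataset,
                      config_means: dict[str, float] | None = None,
                      z: float = 2.5) -> dict:
    """Learning-phase confound features for the A2-preference checks:
    per-arm choice counts, the A2-A1 frequency difference, and per-arm sums
    of observed rewards beyond mu +/- z*sigma of the arm's distribution."""
    means = config_means or {"A1": 64.0, "B": 54.0, "A2": 64.0, "C": 44.0}
    sigmas = dataset.meta.get("sigmas", {k: 13.0 for k in means})
    learn = dataset.phase(LEARNING)
    answered = learn[learn["choice"].notna() & (learn["choice"] != "")]
    counts = {s: int((answered["choice"] == s).sum()) for s in means}
    upper = {s: 0.0 for s in means}
    lower = {s: 0.0 for s in means}
    for row in answered.itertuples(index=False):
        s, r = row.choice, row.r_chosen
        if r != r:
            continue
        if r > means[s] + z * sigmas[s]:
            upper[s] += r
        elif r < means[s] - z * sigmas[s]:
            lower[s] += r
    return {
        "choice_counts": counts,
        "freq_diff_a2_a1": counts["A2"] - counts["A1"],
        "upper_tail_sums": upper,
        "lower_tail_sums": lower,
    }


def logistic_confound_test(y, x):
    """Single-predictor + intercept ML logistic regression (the cohort-level
    check that a confound feature does not explain the A2 preference).
    Returns coefficient estimates with Wald SEs and p-values."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    design = sm.add_constant(np.asarray(x, dtype=float))
    res = sm.Logit(y, design).fit(disp=0)
    return pd.DataFrame({
        "coef": res.params, "se": res.bse, "z": res.tvalues, "p_value": res.pvalues,
    }, index=["intercept", "predictor"])


def cohort_summary(cohort: list[BehavioralDataset],
                   config_means: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-subject learning/transfer accuracy, A2 indicators, and confound
    features in one table."""
    rows = []
    for ds in cohort:
        learn_perf, _ = performance(ds, LEARNING, config_means)
        trans_perf, _ = performance(ds, TRANSFER, config_means)
        bias = _first_and_rate_a2(ds)
        feats = confound_features(ds, config_means)
        rows.append({
            "subject": ds.subject_id,
            "learning_accuracy": learn_perf,
            "transfer_accuracy": trans_perf,
            "first_a2_over_a1": None if bias is None else bias[0],
            "a2_rate": None if bias is None else bias[1],
            "freq_diff_a2_a1": feats["freq_diff_a2_a1"],
            "upper_sum_a1": feats["upper_tail_sums"]["A1"],
            "upper_sum_a2": feats["upper_tail_sums"]["A2"],
            "lower_sum_a1": feats["lower_tail_sums"]["A1"],
            "lower_sum_a2": feats["lower_tail_sums"]["A2"],
        })
    return pd.DataFrame(rows)
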