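"""Synthetic cohorts and pure model simulations.

Agents of any registered family play the three-phase task; cohorts sample
their parameters from beta distributions (explicit shapes or moment-matched
to a mean±SD table). Two pure-simulation experiments characterise the
opposing-learning mechanism: the anti-correlation of paired option values
(corr(Q1,Q2) ~ -alpha2/alpha1) and the performance gain from raising
alpha2/alpha1.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import task_env
from .models import AgentState, Feedback, ModelParams, get_model, \
    sbe_trial_likelihood, softmax_choice_prob
from .task_env import (COMPLETE, ESTIMATION, LEARNING, PARTIAL, TRANSFER,
                       TaskConfig, default_config, draw_reward)

COLUMNS = ["subject", "phase", "trial", "context", "stim_left", "stim_right",
           "choice", "r_chosen", "r_unchosen", "confidence", "estimate"]

__all__ = [
    "BehavioralDataset", "GridSpec", "ParamSampler", "beta_moments_to_shapes",
    "simulate_agent", "simulate_cohort", "qvalue_correlation_experiment",
    "run_performance_grid", "write_dataset", "read_dataset",
    "write_cohort", "read_cohort",
]


@dataclass
class BehavioralDataset:
    """Per-trial log of one subject across the three phases, plus generating
    truth metadata when synthetic."""

    subject_id: str
    regime: str
    trials: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def excluded(self) -> bool:
        return bool(self.meta.get("excluded", False))

    def phase(self, name: str) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == name]

    def validate(self) -> "BehavioralDataset":
        missing = [c for c in COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        n_learn = len(self.phase(LEARNING))
        if not self.excluded and not 100 <= n_learn <= 300:
            raise ValueError(f"learning phase has {n_learn} trials, expected [100, 300]")
        if len(self.phase(TRANSFER)) != 24:
            raise ValueError("transfer phase must have 24 trials")
        if len(self.phase(ESTIMATION)) != 16:
            raise ValueError("estimation phase must have 16 trials")
        learn = self.phase(LEARNING)
        answered = learn["choice"].notna()
        has_cf = learn.loc[answered, "r_unchosen"].notna()
        if self.regime == COMPLETE and not has_cf.all():
            raise ValueError("complete-feedback dataset missing counterfactual rewards")
        if self.regime == PARTIAL and has_cf.any():
            raise ValueError("partial-feedback dataset carries counterfactual rewards")
        return self


def _choice_prob(spec, state: AgentState, a: str, b: str, params: ModelParams,
                 init_q: float) -> float:
    """P(choose a over b) for the given model family."""
    if spec.uses_history:
        return sbe_trial_likelihood(state.history, state.t, a, b,
                                    params.alpha1, params.beta, init_value=init_q)
    return softmax_choice_prob(state.q[a], state.q[b], params.beta)


def simulate_agent(model_key: str, params: ModelParams, config: TaskConfig,
                   seed) -> BehavioralDataset:
    """One agent playing the full task.

    Learning-phase choices are softmax on the model's running values with
    trial-by-trial updating and the adaptive stopping rule; transfer choices
    are softmax on the frozen end-of-learning values (no feedback, no
    updating); estimation responses are frozen values plus response noise,
    clipped to the 0-100 display scale. The stopping rule compares the means
    of all rewards the agent has observed for A1 and A2 (factual only under
    partial feedback; factual and counterfactual under complete).
    """
    spec = get_model(model_key, config.feedback_regime)
    params.validate()
    regime = config.feedback_regime
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng_sched, rng_play, rng_est = [np.random.default_rng(s) for s in ss.spawn(3)]

    schedule = task_env.build_learning_schedule(config, rng_sched)
    transfer_sched, estim_sched = task_env.build_eval_schedules(config, rng_sched)

    state = AgentState.fresh(config.init_q)
    options = config.options
    seen = {"A1": [], "A2": []}
    rows = []
    excluded = False
    for t, trial in enumerate(schedule, start=1):
        state.t = t
        a, b = trial.stimuli
        p_a = _choice_prob(spec, state, a, b, params, config.init_q)
        chosen, unchosen = (a, b) if rng_play.random() < p_a else (b, a)
        r_ch = draw_reward(options[chosen], rng_play)
        r_un = draw_reward(options[unchosen], rng_play) if regime == COMPLETE else None
        fb = Feedback(chosen, unchosen, r_ch, r_un)
        spec.step(state, fb, params, regime)
        for stim, r in ((chosen, r_ch), (unchosen, r_un)):
            if stim in seen and r is not None:
                seen[stim].append(r)
        rows.append((LEARNING, t, fb.context, trial.left, trial.right,
                     chosen, r_ch, r_un, None, None))
        try:
            decision = task_env.stopping_decision(seen["A1"], seen["A2"], t, config)
        except task_env.DegenerateHistoryError:
            # one of A1/A2 never sampled (an exploitation lock-in): the
            # criterion cannot be evaluated, so the phase runs to max_trials
            # and the subject is excluded there
            decision = "exclude" if t >= config.max_trials else "continue"
        if decision == "stop":
            break
        if decision == "exclude":
            excluded = True
            break

    n_learning = len(rows)
    state.t = n_learning + 1   # transfer choices sample from the full history
    for t, trial in enumerate(transfer_sched, start=1):
        a, b = trial.stimuli
        p_a = _choice_prob(spec, state, a, b, params, config.init_q)
        chosen = a if rng_play.random() < p_a else b
        rows.append((TRANSFER, t, f"{a}{b}", trial.left, trial.right,
                     chosen, None, None, None, None))
    estimates = {}
    for t, trial in enumerate(estim_sched, start=1):
        stim = trial.stimuli[0]
        if spec.uses_history:
            hist = state.history[stim]
            truth = np.mean([r for _, r in hist]) if hist else config.init_q
        else:
            truth = state.q[stim]
        est = float(np.clip(truth + rng_est.normal(0.0, config.estimation_noise_sd),
                            0.0, 100.0))
        estimates[t] = est
        rows.append((ESTIMATION, t, stim, stim, None, None, None, None, None, est))

    trials = pd.DataFrame(rows, columns=COLUMNS[1:])
    for col in ("r_chosen", "r_unchosen", "confidence", "estimate"):
        trials[col] = trials[col].astype("float64")
    trials.insert(0, "subject", "sim")
    meta_params = {k: getattr(params, k) for k in spec.fit_params(regime)
                   if k != "a2_ratio"}
    if "a2_ratio" in spec.fit_params(regime):
        meta_params["a2_ratio"] = params.alpha2 / params.alpha1 if params.alpha1 else 0.0
    meta = {
        "model": model_key,
        "regime": regime,
        "params": meta_params,
        "seed": int(ss.entropy) if np.ndim(ss.entropy) == 0 else list(ss.entropy),
        "excluded": excluded,
        "n_learning": n_learning,
        "final_q": {s: state.q[s] for s in config.stimuli},
    }
    if model_key == "OL2":
        meta_params["alpha2"] = params.alpha2
    return BehavioralDataset("sim", regime, trials, meta)


# ---------------------------------------------------------------------------
# cohort parameter samplers

def beta_moments_to_shapes(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) shapes matching a mean±SD on [0, 1].

    Raises if the SD is infeasible for the mean (variance >= mean*(1-mean)).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean {mean} must be inside (0, 1)")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(f"sd {sd} infeasible for mean {mean} on [0, 1]")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class ParamSampler:
    """Independent beta distributions over a model's fit-space coordinates.

    Built either from explicit shape pairs or moment-matched to a mean±SD
    table of fitted-parameter summaries.
    """

    model_key: str
    regime: str
    shapes: dict[str, tuple[float, float]]

    @classmethod
    def from_moments(cls, model_key: str, regime: str,
                     moments: dict[str, tuple[float, float]]) -> "ParamSampler":
        shapes = {}
        for name, (mean, sd) in moments.items():
            try:
                shapes[name] = beta_moments_to_shapes(mean, sd)
            except ValueError as err:
                raise ValueError(f"parameter {name!r}: {err}") from err
        return cls(model_key, regime, shapes)

    def sample(self, rng: np.random.Generator) -> ModelParams:
        spec = get_model(self.model_key, self.regime)
        names = spec.fit_params(self.regime)
        missing = [n for n in names if n not in self.shapes]
        if missing:
            raise ValueError(f"sampler for {self.model_key} missing {missing}")
        vec = [rng.beta(*self.shapes[n]) for n in names]
        return spec.to_params(vec, self.regime)


# Fitted-parameter summaries (mean, SD) used to generate realistic cohorts.
# FQL is not part of the summarised main model space; its entries are the
# package's own realistic choices (documented in docs/methods.md).
FITTED_PARAM_MOMENTS = {
    (PARTIAL, "SQL"): {"beta": (0.07, 0.03), "alpha1": (0.25, 0.26)},
    (PARTIAL, "RPA"): {"beta": (0.12, 0.08), "alpha1": (0.26, 0.27), "alpha2": (0.34, 0.30)},
    (PARTIAL, "Hyb"): {"beta": (0.06, 0.04), "alpha1": (0.37, 0.29), "w": (0.55, 0.37)},
    (PARTIAL, "OL1"): {"beta": (0.02, 0.02), "alpha1": (0.26, 0.20)},
    (PARTIAL, "OL2"): {"beta": (0.03, 0.02), "alpha1": (0.32, 0.23), "a2_ratio": (0.60, 0.25)},
    (PARTIAL, "FQL"): {"beta": (0.07, 0.03), "alpha1": (0.25, 0.20), "alpha2": (0.80, 0.15)},
    (COMPLETE, "SQL"): {"beta": (0.12, 0.09), "alpha1": (0.14, 0.16)},
    (COMPLETE, "RPA"): {"beta": (0.37, 0.24), "alpha1": (0.10, 0.12), "alpha2": (0.11, 0.13),
                        "alpha3": (0.35, 0.30)},
    (COMPLETE, "Dif"): {"beta": (0.37, 0.23), "alpha1": (0.09, 0.08)},
    (COMPLETE, "Hyb"): {"beta": (0.20, 0.15), "alpha1": (0.21, 0.15), "w": (0.28, 0.23)},
    (COMPLETE, "OL1"): {"beta": (0.11, 0.12), "alpha1": (0.22, 0.15), "w": (0.28, 0.17)},
    (COMPLETE, "OL2"): {"beta": (0.10, 0.10), "alpha1": (0.26, 0.14), "a2_ratio": (0.70, 0.20),
                        "w": (0.32, 0.19)},
    (COMPLETE, "FQL"): {"beta": (0.12, 0.09), "alpha1": (0.14, 0.14), "alpha2": (0.80, 0.15)},
}


def default_sampler(model_key: str, regime: str) -> ParamSampler:
    try:
        moments = FITTED_PARAM_MOMENTS[(regime, model_key)]
    except KeyError:
        raise KeyError(f"no fitted-parameter summary for {model_key}/{regime}")
    return ParamSampler.from_moments(model_key, regime, moments)


def simulate_cohort(model_key: str, sampler: ParamSampler | None, n_subjects: int,
                    config: TaskConfig, seed,
                    skip_excluded: bool = False) -> list[BehavioralDataset]:
    """n independent agents with parameters drawn per subject.

    ``skip_excluded`` keeps drawing fresh agents until n non-excluded runs
    exist (mirrors the study's exclusion of subjects whose experienced A1/A2
    means never converged).
    """
    if sampler is None:
        sampler = default_sampler(model_key, config.feedback_regime)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    cohort: list[BehavioralDataset] = []
    attempt = 0
    while len(cohort) < n_subjects:
        attempt += 1
        if attempt > max(20, 10 * n_subjects):
            raise RuntimeError("too many excluded runs while building cohort")
        params = sampler.sample(rng)
        child = np.random.SeedSequence(entropy=ss.entropy,
                                       spawn_key=tuple(ss.spawn_key) + (1, attempt))
        ds = simulate_agent(model_key, params, config, child)
        if ds.excluded and skip_excluded:
            continue
        ds.subject_id = f"{model_key}-{len(cohort):03d}"
        ds.trials["subject"] = ds.subject_id
        ds.meta["subject"] = ds.subject_id
        cohort.append(ds)
    return cohort


# ---------------------------------------------------------------------------
# pure simulations (normalized two-option context, plain normal rewards)

def _simulate_ol_pair(alpha1, alpha2, beta, means, n_trials, n_runs, rng,
                      record_q=False):
    """Vectorised opposing-learning runs on one isolated option pair.

    Rewards are plain normals with SD 1 (the normalised simulation scale).
    Returns (choices[n_runs, n_trials], q_series[n_runs, n_trials, 2] | None).
    """
    mu = np.asarray(means, dtype=float)
    q = np.zeros((n_runs, 2))
    choices = np.empty((n_runs, n_trials), dtype=np.int8)
    q_series = np.empty((n_runs, n_trials, 2)) if record_q else None
    for t in range(n_trials):
        z = beta * (q[:, 1] - q[:, 0])
        p0 = np.where(z >= 0, np.exp(-np.clip(z, 0, None)) / (1 + np.exp(-np.clip(z, 0, None))),
                      1.0 / (1 + np.exp(np.clip(z, None, 0))))
        ch = (rng.random(n_runs) >= p0).astype(np.int8)   # 0 or 1
        r = rng.normal(mu[ch], 1.0)
        delta = r - q[np.arange(n_runs), ch]
        q[np.arange(n_runs), ch] += alpha1 * delta
        q[np.arange(n_runs), 1 - ch] -= alpha2 * delta
        choices[:, t] = ch
        if record_q:
            q_series[:, t, :] = q
    return choices, q_series


def qvalue_correlation_experiment(alpha1, alpha2, beta, pair_means=(7.0, 5.0),
                                  n_trials=1000, n_runs=20, seed=0,
                                  burn_in=None):
    """Pearson correlation between the two Q-value time series of a pair.

    Computed within each run over the post-burn-in trials, then averaged
    across runs; the Monte-Carlo standard error is over runs. Returns a dict
    with per-run correlations, their mean and SE.

    The default burn-in adapts to the slowest mode of the value dynamics:
    the sum Q1+Q2 relaxes at roughly (alpha1-alpha2)/2 per trial (it is
    exactly conserved at alpha2 = alpha1), so a fixed short burn-in leaves
    transient contamination at intermediate alpha2/alpha1 ratios. At least
    50 trials are always discarded; pass ``burn_in`` to fix it.
    """
    if burn_in is None:
        gap = 0.5 * max(alpha1 - alpha2, 0.0)
        slow = 6.0 / gap if gap > 0 else 0.0
        burn_in = int(min(max(50, slow), n_trials // 2))
    if n_trials <= burn_in + 2:
        raise ValueError("n_trials must exceed burn_in + 2")
    rng = np.random.default_rng(seed)
    _, q_series = _simulate_ol_pair(alpha1, alpha2, beta, pair_means,
                                    n_trials, n_runs, rng, record_q=True)
    qs = q_series[:, burn_in:, :]
    per_run = np.empty(n_runs)
    for i in range(n_runs):
        q1, q2 = qs[i, :, 0], qs[i, :, 1]
        s1, s2 = q1.std(), q2.std()
        per_run[i] = np.corrcoef(q1, q2)[0, 1] if s1 > 0 and s2 > 0 else 0.0
    se = per_run.std(ddof=1) / np.sqrt(n_runs) if n_runs >= 2 else float("nan")
    # alternative estimator: one correlation over all runs' series pooled
    pooled = float(np.corrcoef(qs[:, :, 0].ravel(), qs[:, :, 1].ravel())[0, 1])
    return {"per_run": per_run, "mean": float(per_run.mean()), "se": float(se),
            "pooled": pooled, "n_runs": n_runs, "n_trials": n_trials}


@dataclass(frozen=True)
class GridSpec:
    """Normalised pure-simulation grid: isolated pairs with SD-1 rewards."""

    pair_means: tuple[tuple[float, float], ...] = ((10.0, 7.0),)
    betas: tuple[float, ...] = (0.1,)
    alpha1s: tuple[float, ...] = (0.2,)
    ratios: tuple[float, ...] = (0.0, 0.5, 1.0)   # alpha2/alpha1
    n_trials: int = 200
    n_reps: int = 200

    def __post_init__(self) -> None:
        if not (self.pair_means and self.betas and self.alpha1s and self.ratios):
            raise ValueError("grid axes must be non-empty")
        if any(not 0.0 <= r <= 1.0 for r in self.ratios):
            raise ValueError("ratios must lie in [0, 1]")


def run_performance_grid(grid: GridSpec, seed=0) -> pd.DataFrame:
    """Mean±SD fraction of higher-mean choices per grid cell.

    ratio 0 is standard Q-learning; ratio 1 is opposing learning with equal
    rates. The SE column is the Monte-Carlo standard error over repetitions.
    """
    rows = []
    for im, means in enumerate(grid.pair_means):
        best = int(np.argmax(means))
        for ib, beta in enumerate(grid.betas):
            for ia, a1 in enumerate(grid.alpha1s):
                for ratio in grid.ratios:
                    # matched reward/choice noise across the ratio axis so the
                    # alpha2/alpha1 comparison uses common random numbers
                    rng = np.random.default_rng([seed, im, ib, ia])
                    choices, _ = _simulate_ol_pair(
                        a1, ratio * a1, beta, means, grid.n_trials,
                        grid.n_reps, rng)
                    acc = (choices == best).mean(axis=1)
                    rows.append({
                        "mu_hi": max(means), "mu_lo": min(means), "beta": beta,
                        "alpha1": a1, "ratio": ratio,
                        "mean_perf": float(acc.mean()),
                        "sd_perf": float(acc.std(ddof=1)),
                        "se_perf": float(acc.std(ddof=1) / np.sqrt(grid.n_reps)),
                        "n_reps": grid.n_reps, "n_trials": grid.n_trials,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV dialect

def _meta_lines(meta: dict) -> list[str]:
    return [f"# {k}={json.dumps(v)}" for k, v in meta.items()]


def write_dataset(dataset: BehavioralDataset, path) -> None:
    """UTF-8 CSV, metadata in '#'-prefixed key=json lines before the header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# regime={json.dumps(dataset.regime)}\n")
        for line in _meta_lines(dataset.meta):
            fh.write(line + "\n")
        dataset.trials.to_csv(fh, index=False, na_rep="")


def _parse_meta(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" not in body:
            continue
        key, _, raw = body.partition("=")
        try:
            meta[key.strip()] = json.loads(raw)
        except json.JSONDecodeError:
            meta[key.strip()] = raw
    return meta


def _read_csv_block(path):
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    meta_lines = [l for l in text.splitlines() if l.startswith("#")]
    meta = _parse_meta(meta_lines)
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    trials = pd.read_csv(
        io.StringIO(body),
        dtype={"subject": str, "phase": str, "context": str, "stim_left": str,
               "stim_right": str, "choice": str},
    )
    missing = [c for c in COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_phase = set(trials["phase"].unique()) - {LEARNING, TRANSFER, ESTIMATION}
    if bad_phase:
        rows = trials.index[trials["phase"].isin(bad_phase)] + len(meta_lines) + 2
        raise ValueError(f"{path}: unknown phase values {sorted(bad_phase)} "
                         f"(first offending line {rows[0]})")
    return meta, trials


def read_dataset(path) -> BehavioralDataset:
    meta, trials = _read_csv_block(path)
    regime = meta.get("regime")
    if regime not in (PARTIAL, COMPLETE):
        raise ValueError(f"{path}: unknown or missing regime {regime!r}")
    subject = meta.get("subject") or str(trials["subject"].iloc[0])
    return BehavioralDataset(subject, regime, trials, meta).validate()


def write_cohort(cohort: list[BehavioralDataset], path) -> None:
    """All subjects in one file; per-subject truth metadata keyed by id."""
    if not cohort:
        raise ValueError("empty cohort")
    meta = {"regime": cohort[0].regime,
            "subjects": {d.subject_id: d.meta for d in cohort}}
    frames = pd.concat([d.trials for d in cohort], ignore_index=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        frames.to_csv(fh, index=False, na_rep="")


def read_cohort(path) -> list[BehavioralDataset]:
    meta, trials = _read_csv_block(path)
    regime = meta.get("regime")
    if regime not in (PARTIAL, COMPLETE):
        raise ValueError(f"{path}: unknown or missing regime {regime!r}")
    per_subject = meta.get("subjects", {})
    cohort = []
    for sid, df in trials.groupby("subject", sort=False):
        ds = BehavioralDataset(str(sid), regime, df.reset_index(drop=True),
                               per_subject.get(str(sid), {"subject": sid}))
        cohort.append(ds.validate())
    return cohort
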