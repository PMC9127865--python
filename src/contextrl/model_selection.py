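"""Random-effects Bayesian model selection and recovery studies.

``random_effects_bms`` implements the variational scheme for group-level
model comparison: model frequencies get a Dirichlet posterior (uniform prior
concentration 1), per-subject model assignments a categorical posterior, and
the two are iterated to convergence. Exceedance probabilities (xp) are the
posterior mass on each model being the most frequent; protected exceedance
probabilities (pxp) blend xp with chance according to the Bayes omnibus risk
(BOR), the posterior probability that frequencies are exactly uniform.
Evidence enters as -BIC/2 per subject and model.

The recovery studies close the loop on the fitting pipeline: simulate
cohorts from known models/parameters, refit, and tabulate either the
winner-confusion matrices p(fit|gen) and p(gen|fit) (model recovery, AIC
winners, uniform prior over generators) or per-parameter correlation and
regression of recovered against true values (parameter recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc, digamma, gammaln, logsumexp

from .fitting import map_fit
from .synthetic_data import ParamSampler, default_sampler, simulate_cohort
from .task_env import TaskConfig

__all__ = ["BMSResult", "RecoveryReport", "random_effects_bms",
           "model_recovery_study", "parameter_recovery_study",
           "confusion_to_posterior"]


@dataclass
class BMSResult:
    models: tuple[str, ...]
    alpha_posterior: np.ndarray      # Dirichlet concentrations
    expected_frequencies: np.ndarray
    xp: np.ndarray
    pxp: np.ndarray
    bor: float
    assignment: np.ndarray           # subjects x models posterior


@dataclass
class RecoveryReport:
    models: tuple[str, ...]
    p_fit_given_gen: pd.DataFrame | None = None
    p_gen_given_fit: pd.DataFrame | None = None
    param_table: pd.DataFrame | None = None   # per-parameter r, b0, b1, SEs
    params_true: pd.DataFrame | None = None
    params_recovered: pd.DataFrame | None = None
    n_failures: int = 0


def _dirichlet_free_energy(log_evidence, u, alpha, alpha0):
    """Variational free energy of the random-effects model (H1)."""
    e_logr = digamma(alpha) - digamma(alpha.sum())
    f = float(np.sum(u * (log_evidence + e_logr[None, :])))
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(u > 0, u * np.log(u), 0.0))
    f += ent
    f += float(gammaln(alpha0.sum()) - gammaln(alpha0).sum()
               + np.sum((alpha0 - 1.0) * e_logr))
    f -= float(gammaln(alpha.sum()) - gammaln(alpha).sum()
               + np.sum((alpha - 1.0) * e_logr))
    return f


def _xp_from_dirichlet(alpha, rng, n_samples):
    m = len(alpha)
    if m == 2:
        # analytic: P(r1 > 1/2) under Beta(alpha1, alpha2)
        p1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p1, 1.0 - p1])
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=m) / n_samples


def random_effects_bms(log_evidence, models=None, seed=0, n_samples=1_000_000,
                       max_iter=200, tol=1e-8) -> BMSResult:
    """Group-level model comparison from a subjects x models log-evidence
    matrix (use -BIC/2 as the evidence proxy)."""
    le = np.asarray(log_evidence, dtype=float)
    if le.ndim != 2 or le.shape[0] < 1 or le.shape[1] < 2:
        raise ValueError("need a subjects x models matrix with >= 2 models")
    if not np.isfinite(le).all():
        bad = np.argwhere(~np.isfinite(le))[0]
        raise ValueError(f"non-finite evidence at subject {bad[0]}, model {bad[1]}")
    n, m = le.shape
    models = tuple(models) if models is not None else tuple(f"m{i}" for i in range(m))
    alpha0 = np.ones(m)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        e_logr = digamma(alpha) - digamma(alpha.sum())
        logu = le + e_logr[None, :]
        u = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    e_logr = digamma(alpha) - digamma(alpha.sum())
    logu = le + e_logr[None, :]
    u = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))

    rng = np.random.default_rng(seed)
    xp = _xp_from_dirichlet(alpha, rng, n_samples)

    # BOR: H1 (frequencies free) vs H0 (uniform frequencies)
    f1 = _dirichlet_free_energy(le, u, alpha, alpha0)
    f0 = float(np.sum(logsumexp(le - np.log(m), axis=1)))
    bor = 1.0 / (1.0 + np.exp(f1 - f0))
    pxp = (1.0 - bor) * xp + bor / m
    return BMSResult(models=models, alpha_posterior=alpha,
                     expected_frequencies=alpha / alpha.sum(),
                     xp=xp, pxp=pxp, bor=float(bor), assignment=u)


def confusion_to_posterior(p_fit_given_gen: pd.DataFrame) -> pd.DataFrame:
    """Bayes inversion with a uniform prior over generating models:
    p(gen|fit) column-normalises p(fit|gen)."""
    mat = p_fit_given_gen.to_numpy(dtype=float)
    col = mat.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(col > 0, mat / col, np.nan)
    return pd.DataFrame(post, index=p_fit_given_gen.index,
                        columns=p_fit_given_gen.columns)


def _fit_cohort(models, cohort, n_restarts, rng, failures, max_failure_rate=0.05,
                total_planned=None, init_q=0.0):
    """AIC table (subjects x models); failures are recorded and excluded."""
    aic = np.full((len(cohort), len(models)), np.nan)
    for i, ds in enumerate(cohort):
        for j, key in enumerate(models):
            try:
                fr = map_fit(key, ds, n_restarts=n_restarts,
                             seed=int(rng.integers(2**31)), init_q=init_q)
                aic[i, j] = fr.aic
            except Exception as err:     # recorded, capped below
                failures.append(f"{ds.subject_id}/{key}: {err}")
        if total_planned and len(failures) > max_failure_rate * total_planned:
            raise RuntimeError(f"fit failure rate exceeded 5%: {failures[:5]}")
    return aic


def model_recovery_study(model_keys, cohort_size: int, repetitions: int,
                         config: TaskConfig, seed=0, n_restarts: int = 3,
                         samplers: dict[str, ParamSampler] | None = None
                         ) -> RecoveryReport:
    """Simulate cohorts from each generating model, refit all candidates,
    and tabulate the AIC-winner confusion matrices."""
    model_keys = tuple(model_keys)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    regime = config.feedback_regime
    counts = np.zeros((len(model_keys), len(model_keys)))
    failures: list[str] = []
    total = len(model_keys) * repetitions * cohort_size * len(model_keys)
    for gi, gen_key in enumerate(model_keys):
        sampler = (samplers or {}).get(gen_key) or default_sampler(gen_key, regime)
        for rep in range(repetitions):
            cohort = simulate_cohort(
                gen_key, sampler, cohort_size, config,
                seed=np.random.SeedSequence(entropy=seed, spawn_key=(gi, rep)),
                skip_excluded=True)
            aic = _fit_cohort(model_keys, cohort, n_restarts, rng, failures,
                              total_planned=total, init_q=config.init_q)
            for row in aic:
                if np.isnan(row).any():
                    continue
                counts[gi, int(np.argmin(row))] += 1.0
    row_sums = counts.sum(axis=1, keepdims=True)
    p_fit = np.where(row_sums > 0, counts / row_sums, np.nan)
    p_fit_df = pd.DataFrame(p_fit, index=list(model_keys), columns=list(model_keys))
    return RecoveryReport(models=model_keys, p_fit_given_gen=p_fit_df,
                          p_gen_given_fit=confusion_to_posterior(p_fit_df),
                          n_failures=len(failures))


def parameter_recovery_study(model_key: str, sampler: ParamSampler | None,
                             cohort_size: int, repetitions: int,
                             config: TaskConfig, seed=0, n_restarts: int = 10
                             ) -> RecoveryReport:
    """Simulate -> refit the generating model -> per-parameter Pearson r and
    the regression recovered = b0 + b1 * true."""
    from .models import get_model

    regime = config.feedback_regime
    spec = get_model(model_key, regime)
    names = spec.fit_params(regime)
    sampler = sampler or default_sampler(model_key, regime)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    true_rows, rec_rows = [], []
    failures: list[str] = []
    for rep in range(repetitions):
        cohort = simulate_cohort(
            model_key, sampler, cohort_size, config,
            seed=np.random.SeedSequence(entropy=seed, spawn_key=(7, rep)),
            skip_excluded=True)
        for ds in cohort:
            try:
                fr = map_fit(model_key, ds, n_restarts=n_restarts,
                             seed=int(rng.integers(2**31)), init_q=config.init_q)
            except Exception as err:
                failures.append(f"{ds.subject_id}: {err}")
                if len(failures) > 0.05 * repetitions * cohort_size + 1:
                    raise RuntimeError("fit failure rate exceeded 5%") from err
                continue
            truth = ds.meta["params"]
            true_rows.append({n: truth.get(n, np.nan) for n in names})
            rec_rows.append(dict(zip(names, fr.map_vector)))
    true_df = pd.DataFrame(true_rows)
    rec_df = pd.DataFrame(rec_rows)
    # OL2's ratio coordinate maps back to alpha2 for reporting
    table = []
    for n in names:
        x = true_df[n].to_numpy(float)
        y = rec_df[n].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            table.append({"param": n, "r": np.nan, "b0": np.nan, "b1": np.nan,
                          "b0_se": np.nan, "b1_se": np.nan, "note": "degenerate"})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        res = stats.linregress(x, y)
        table.append({"param": n, "r": r, "b0": float(res.intercept),
                      "b1": float(res.slope), "b0_se": float(res.intercept_stderr),
                      "b1_se": float(res.stderr), "note": ""})
    return RecoveryReport(models=(model_key,), param_table=pd.DataFrame(table),
                          params_true=true_df, params_recovered=rec_df,
                          n_failures=len(failures))
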