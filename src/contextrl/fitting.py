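"""Per-subject likelihoods, MAP estimation, information criteria, and
transfer-phase predictive scoring.

Fitting minimises the learning-phase negative log-likelihood penalised by a
weakly informative Beta(1.2, 1.2) prior on every fit-space coordinate, over
box constraints, from several prior-sampled starts (L-BFGS-B). The inverse
temperature is fitted on [0, 1]: option values live on a 0-100 point scale,
so plausible beta values are far below 1 (the bound is configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._kernels import (STIM_INDEX, pack_learning_trials, params_to_vector,
                       python_replay_nll, replay_nll)
from .models import ModelParams, get_model, sbe_trial_likelihood, softmax_choice_prob
from .synthetic_data import BehavioralDataset
from .task_env import COMPLETE, LEARNING, STIMULI, TRANSFER

PRIOR_A = PRIOR_B = 1.2
_EDGE = 1e-6

__all__ = ["FitResult", "learning_nll", "map_fit", "information_criteria",
           "transfer_nll"]


@dataclass
class FitResult:
    subject_id: str
    model_key: str
    regime: str
    map_params: ModelParams
    map_vector: np.ndarray            # fit-space coordinates of the optimum
    learning_nll: float               # nats, at the MAP point
    learning_map_objective: float     # nll - log prior, at the MAP point
    bic: float
    aic: float
    n_trials_used: int
    n_restarts: int = 1
    best_restart_index: int = 0
    transfer_nll_total: float | None = None
    transfer_nll_a1a2: float | None = None


def _packed(dataset: BehavioralDataset):
    cache = getattr(dataset, "_packed_cache", None)
    if cache is None:
        cache = pack_learning_trials(dataset.phase(LEARNING))
        dataset._packed_cache = cache
    return cache


def _nll_packed(spec, params: ModelParams, packed, regime: str, init_q: float):
    if spec.kernel_id >= 0:
        nll, q = replay_nll(spec.kernel_id, regime == COMPLETE,
                            params_to_vector(params), packed["chosen"],
                            packed["unchosen"], packed["r_ch"], packed["r_un"],
                            init_q)
        return float(nll), q
    nll, q, _ = python_replay_nll(spec, params, packed, regime, init_q)
    return float(nll), q


def learning_nll(model_key: str, params: ModelParams, dataset: BehavioralDataset,
                 init_q: float = 0.0) -> float:
    """Summed -log softmax probability of the observed learning-phase choices,
    replaying the model's updates trial by trial. Missed trials contribute no
    likelihood term and no state update (no outcome was delivered)."""
    spec = get_model(model_key, dataset.regime)
    params.validate()
    packed = _packed(dataset)
    if not (packed["chosen"] >= 0).any():
        raise ValueError("dataset has no answered learning trials")
    nll, _ = _nll_packed(spec, params, packed, dataset.regime, init_q)
    return nll


def information_criteria(nll: float, k: int, n: int) -> tuple[float, float]:
    """BIC = 2*nll + k*ln(n); AIC = 2*nll + 2*k. n is answered trials, so the
    per-subject adaptive phase length is accounted for."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * nll + k * math.log(n), 2.0 * nll + 2.0 * k


def _log_prior(vec: np.ndarray) -> float:
    return float(np.sum(stats.beta.logpdf(vec, PRIOR_A, PRIOR_B)))


def map_fit(model_key: str, dataset: BehavioralDataset, n_restarts: int = 10,
            seed=0, init_q: float = 0.0, tol: float = 1e-8,
            use_prior: bool = True) -> FitResult:
    """MAP estimate from the best of ``n_restarts`` prior-sampled starts.

    ``use_prior=False`` drops the Beta(1.2, 1.2) penalty and fits by maximum
    likelihood (useful for nested-model likelihood comparisons, where the
    prior's boundary repulsion would otherwise keep a richer model away from
    the parameter edge embedding the nested one).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    spec = get_model(model_key, dataset.regime)
    regime = dataset.regime
    packed = _packed(dataset)
    answered = int((packed["chosen"] >= 0).sum())
    if answered == 0:
        raise ValueError("dataset has no answered learning trials")
    k = spec.n_params(regime)
    rng = np.random.default_rng(seed)

    def objective(vec):
        vec = np.clip(vec, _EDGE, 1.0 - _EDGE)
        params = spec.to_params(vec, regime)
        nll, _ = _nll_packed(spec, params, packed, regime, init_q)
        return nll - _log_prior(vec) if use_prior else nll

    bounds = [(_EDGE, 1.0 - _EDGE)] * k
    best = None
    diagnostics = []
    for i in range(n_restarts):
        x0 = rng.beta(PRIOR_A, PRIOR_B, size=k)
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": tol, "maxiter": 500})
        if not np.isfinite(res.fun):
            diagnostics.append(f"restart {i}: non-finite objective")
            continue
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x.copy(), i)
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed for {model_key}: "
                           + "; ".join(diagnostics))
    obj, x, idx = best
    map_params = spec.to_params(x, regime)
    nll, _ = _nll_packed(spec, map_params, packed, regime, init_q)
    bic, aic = information_criteria(nll, k, answered)
    return FitResult(
        subject_id=dataset.subject_id, model_key=model_key, regime=regime,
        map_params=map_params, map_vector=x, learning_nll=float(nll),
        learning_map_objective=obj, bic=bic, aic=aic, n_trials_used=answered,
        n_restarts=n_restarts, best_restart_index=idx,
    )


def transfer_nll(model_key: str, fit: FitResult, dataset: BehavioralDataset,
                 init_q: float = 0.0) -> tuple[float, float]:
    """Predictive NLL of the transfer choices under frozen end-of-learning
    values and the learning-phase MAP beta.

    Returns (total over all 24 trials, (A1, A2)-pair subtotal over 4 trials).
    """
    spec = get_model(model_key, dataset.regime)
    transfer = dataset.phase(TRANSFER)
    if transfer.empty:
        raise ValueError("dataset has no transfer phase")
    packed = _packed(dataset)
    params = fit.map_params
    if spec.uses_history:
        _, _, state = python_replay_nll(spec, params, packed, dataset.regime, init_q)
    else:
        _, q = _nll_packed(spec, params, packed, dataset.regime, init_q)
        state = None
    total = 0.0
    a1a2 = 0.0
    n_learn = len(dataset.phase(LEARNING))
    for row in transfer.itertuples(index=False):
        if not isinstance(row.choice, str) or row.choice == "":
            continue
        ch = row.choice
        un = row.stim_left if row.stim_right == ch else row.stim_right
        if state is not None:
            p = sbe_trial_likelihood(state.history, n_learn + 1, ch, un,
                                     params.alpha1, params.beta, init_value=init_q)
        else:
            p = softmax_choice_prob(q[STIM_INDEX[ch]], q[STIM_INDEX[un]], params.beta)
        term = -math.log(p)
        total += term
        if {ch, un} == {"A1", "A2"}:
            a1a2 += term
    return total, a1a2
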