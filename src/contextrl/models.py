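"""Per-trial value-update and likelihood rules for all model families.

Every model shares one state vocabulary (option values Q, context values V,
experience weights N, reward histories) and one choice rule: a softmax on the
two presented option values with inverse temperature beta. The families:

* ``SQL``     standard Q-learning; ``SQLX`` is the extended form that also
              updates the unchosen option from its own (counterfactual) outcome.
* ``RPD/RPA/RPM``  reference-point models: a learned per-context value V_x
              re-centres outcomes before Q-updating; variants differ in the
              contextual reward (direct / average / max).
* ``Dif``     learns the outcome difference r_FC - r_CF (complete feedback only).
* ``Hyb``     hybrid reward: w-weighted mix of absolute reward and outcome
              difference (the unchosen Q stands in for the counterfactual
              outcome under partial feedback).
* ``FQL``     forgetting Q-learning: the unchosen value decays by a factor.
* ``EWA``     experience-weighted attraction with per-option experience weights.
* ``SBE``     sample-based episodic: choice likelihood from recency-weighted
              sampling of past rewards instead of a running value.
* ``RelAsym`` reference point plus confirmation-bias (asymmetric) learning rates.
* ``OL1/OL2`` opposing learning: the chosen prediction error moves the chosen
              value up and the unchosen value down (equal rates in OL1,
              0 < alpha2 <= alpha1 in OL2); under complete feedback the
              prediction error uses the hybrid reward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .task_env import COMPLETE, CONTEXTS, PARTIAL, STIMULI

__all__ = [
    "ModelParams", "AgentState", "Feedback", "ModelSpec", "MODEL_REGISTRY",
    "get_model", "softmax_choice_prob", "softmax_log_prob", "hybrid_reward", "sql_step", "rp_step",
    "dif_step", "hyb_step", "fql_step", "ewa_step", "relasym_step", "ol_step",
    "sbe_trial_likelihood",
]

CONTEXT_OF = {s: f"{a}{b}" for (a, b) in CONTEXTS for s in (a, b)}


class ConfigurationError(ValueError):
    """A model was asked to run in a regime/variant it does not support."""


@dataclass
class ModelParams:
    """Union of all free parameters; each family reads its own subset."""

    beta: float = 0.1          # softmax inverse temperature, >= 0
    alpha1: float = 0.2        # chosen learning rate (SBE: recency rate)
    alpha2: float = 0.0        # second rate: unchosen (OL/SQLX), decay (FQL), Q-rate (RP)
    alpha3: float = 0.0        # RP unchosen rate, complete feedback
    w: float = 1.0             # absolute-strategy weight of the hybrid reward
    rho: float = 0.0           # EWA experience decay
    phi: float = 0.0           # EWA value decay
    delta_imit: float = 0.0    # EWA counterfactual weight (0 under partial feedback)
    alpha_conf: float = 0.0    # confirmatory learning rate (RelAsym)
    alpha_disc: float = 0.0    # disconfirmatory learning rate (RelAsym)

    def validate(self) -> "ModelParams":
        unit = ("alpha1", "alpha2", "alpha3", "w", "rho", "phi", "delta_imit",
                "alpha_conf", "alpha_disc")
        for name in unit:
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name}={x} outside [0, 1]")
        if self.beta < 0:
            raise ValueError(f"beta={self.beta} must be >= 0")
        return self


@dataclass
class AgentState:
    """All latent quantities any family tracks, keyed by stimulus/context label."""

    q: dict[str, float]
    v: dict[str, float] = field(default_factory=dict)
    n: dict[str, float] = field(default_factory=dict)
    history: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    t: int = 0

    @classmethod
    def fresh(cls, init_q: float = 0.0, stimuli=STIMULI) -> "AgentState":
        return cls(
            q={s: float(init_q) for s in stimuli},
            v={f"{a}{b}": 0.0 for a, b in CONTEXTS},
            n={s: 1.0 for s in stimuli},
            history={s: [] for s in stimuli},
        )

    def copy(self) -> "AgentState":
        return AgentState(
            q=dict(self.q), v=dict(self.v), n=dict(self.n),
            history={k: list(v) for k, v in self.history.items()}, t=self.t,
        )


@dataclass(frozen=True)
class Feedback:
    """Outcome of one learning trial (r_unchosen present iff complete feedback)."""

    chosen: str
    unchosen: str
    r_chosen: float
    r_unchosen: float | None = None

    @property
    def context(self) -> str:
        return CONTEXT_OF[self.chosen]


def softmax_choice_prob(q_ch: float, q_un: float, beta: float) -> float:
    """P(choose the option valued q_ch) = 1 / (1 + exp(beta*(q_un - q_ch))).

    Evaluated through the numerically stable branch of the logistic.
    """
    z = beta * (q_un - q_ch)
    if z >= 0:
        return math.exp(-z) / (1.0 + math.exp(-z))
    return 1.0 / (1.0 + math.exp(z))


def softmax_log_prob(q_ch: float, q_un: float, beta: float) -> float:
    """log P(choose) in the overflow-safe log1p form (never -inf from underflow
    unless the gap is truly infinite)."""
    z = beta * (q_un - q_ch)
    if z > 0:
        return -z - math.log1p(math.exp(-z))
    return -math.log1p(math.exp(z))


def hybrid_reward(r_fc: float, counterfactual: float, w: float) -> float:
    """w-weighted mix of absolute reward and outcome difference:
    w*r_fc + (1-w)*(r_fc - counterfactual)."""
    return w * r_fc + (1.0 - w) * (r_fc - counterfactual)


def _require_complete(regime: str, model: str) -> None:
    if regime != COMPLETE:
        raise ConfigurationError(f"{model} requires complete feedback, got {regime!r}")


# ---------------------------------------------------------------------------
# step rules (mutate and return state)

def sql_step(state: AgentState, fb: Feedback, p: ModelParams, regime: str,
             extended: bool = False) -> AgentState:
    q = state.q
    q[fb.chosen] += p.alpha1 * (fb.r_chosen - q[fb.chosen])
    if extended:
        _require_complete(regime, "extended SQL")
        q[fb.unchosen] += p.alpha2 * (fb.r_unchosen - q[fb.unchosen])
    return state


def rp_step(state: AgentState, fb: Feedback, p: ModelParams, variant: str,
            regime: str, update_unchosen: bool = True) -> AgentState:
    """Reference-point update: V_x tracks the contextual reward, Q-values learn
    outcomes re-centred on the updated V_x."""
    q, ctx = state.q, fb.context
    cf = fb.r_unchosen if regime == COMPLETE else q[fb.unchosen]
    if variant == "RPD":
        r_x = fb.r_chosen
    elif variant == "RPA":
        r_x = 0.5 * (fb.r_chosen + cf)
    elif variant == "RPM":
        r_x = max(fb.r_chosen, cf)
    else:
        raise ConfigurationError(f"unknown RP variant {variant!r}")
    state.v[ctx] += p.alpha1 * (r_x - state.v[ctx])
    vx = state.v[ctx]
    q[fb.chosen] += p.alpha2 * ((fb.r_chosen - vx) - q[fb.chosen])
    if regime == COMPLETE and update_unchosen:
        q[fb.unchosen] += p.alpha3 * ((fb.r_unchosen - vx) - q[fb.unchosen])
    return state


def dif_step(state: AgentState, fb: Feedback, p: ModelParams, regime: str) -> AgentState:
    _require_complete(regime, "Dif")
    r_rlt = fb.r_chosen - fb.r_unchosen
    state.q[fb.chosen] += p.alpha1 * (r_rlt - state.q[fb.chosen])
    return state


def hyb_step(state: AgentState, fb: Feedback, p: ModelParams, regime: str) -> AgentState:
    cf = fb.r_unchosen if regime == COMPLETE else state.q[fb.unchosen]
    r_hyb = hybrid_reward(fb.r_chosen, cf, p.w)
    state.q[fb.chosen] += p.alpha1 * (r_hyb - state.q[fb.chosen])
    return state


def fql_step(state: AgentState, fb: Feedback, p: ModelParams, regime: str) -> AgentState:
    q = state.q
    q[fb.chosen] += p.alpha1 * (fb.r_chosen - q[fb.chosen])
    q[fb.unchosen] = p.alpha2 * q[fb.unchosen]
    return state


def ewa_step(state: AgentState, fb: Feedback, p: ModelParams, regime: str) -> AgentState:
    """Experience-weighted attraction with a per-option experience weight N."""
    q, n = state.q, state.n
    n_ch = n[fb.chosen]
    n[fb.chosen] = p.rho * n_ch + 1.0
    q[fb.chosen] = (q[fb.chosen] * n_ch * p.phi + fb.r_chosen) / n[fb.chosen]
    if regime == COMPLETE:
        n_un = n[fb.unchosen]
        n[fb.unchosen] = p.rho * n_un + 1.0
        q[fb.unchosen] = (q[fb.unchosen] * n_un * p.phi
                          + p.delta_imit * fb.r_unchosen) / n[fb.unchosen]
    return state


def relasym_step(state: AgentState, fb: Feedback, p: ModelParams, regime: str,
                 variant: str = "RPD") -> AgentState:
    """Reference point plus asymmetric (confirmation-bias) rates.

    Chosen: confirmatory rate for positive prediction errors. Unchosen
    (complete feedback): confirmatory rate for NEGATIVE prediction errors —
    a drop in the forgone option's value confirms the choice made.
    """
    q, ctx = state.q, fb.context
    cf = fb.r_unchosen if regime == COMPLETE else q[fb.unchosen]
    if variant == "RPD":
        r_x = fb.r_chosen
    elif variant == "RPA":
        r_x = 0.5 * (fb.r_chosen + cf)
    elif variant == "RPM":
        r_x = max(fb.r_chosen, cf)
    else:
        raise ConfigurationError(f"unknown RelAsym variant {variant!r}")
    state.v[ctx] += p.alpha1 * (r_x - state.v[ctx])
    vx = state.v[ctx]
    d_ch = (fb.r_chosen - vx) - q[fb.chosen]
    q[fb.chosen] += (p.alpha_conf if d_ch > 0 else p.alpha_disc) * d_ch
    if regime == COMPLETE:
        d_un = (fb.r_unchosen - vx) - q[fb.unchosen]
        q[fb.unchosen] += (p.alpha_conf if d_un < 0 else p.alpha_disc) * d_un
    return state


def ol_step(state: AgentState, fb: Feedback, p: ModelParams, regime: str) -> AgentState:
    """Opposing learning: one chosen prediction error moves both values of the
    current context, in opposite directions. Complete feedback replaces the
    raw reward with the hybrid reward in the prediction error."""
    q = state.q
    if regime == COMPLETE:
        r = hybrid_reward(fb.r_chosen, fb.r_unchosen, p.w)
    else:
        r = fb.r_chosen
    delta = r - q[fb.chosen]
    q[fb.chosen] += p.alpha1 * delta
    q[fb.unchosen] -= p.alpha2 * delta
    return state


def sbe_append(state: AgentState, fb: Feedback, p: ModelParams, regime: str) -> AgentState:
    """SBE has no incremental value; its 'update' is recording the outcome."""
    state.history[fb.chosen].append((state.t, fb.r_chosen))
    if regime == COMPLETE and fb.r_unchosen is not None:
        state.history[fb.unchosen].append((state.t, fb.r_unchosen))
    return state


def _sbe_weights(samples: list[tuple[int, float]], t: int, alpha: float,
                 init_value: float, normalize: bool) -> tuple[np.ndarray, np.ndarray]:
    if not samples:
        # empty history: one pseudo-sample at the initial value, probability 1
        return np.array([init_value]), np.array([1.0])
    idx = np.array([i for i, _ in samples], dtype=float)
    vals = np.array([r for _, r in samples], dtype=float)
    if np.any(idx >= t):
        raise IndexError("history contains samples at or after the current trial")
    wts = alpha * (1.0 - alpha) ** (t - idx)
    if normalize:
        wts = wts / wts.sum()
    return vals, wts


def sbe_trial_likelihood(history: dict[str, list[tuple[int, float]]], t: int,
                         chosen: str, unchosen: str, alpha: float, beta: float,
                         init_value: float = 0.0, normalize: bool = True) -> float:
    """Recency-weighted sampling likelihood: each option's value is one past
    reward sampled with probability proportional to alpha*(1-alpha)^(t-i);
    the choice probability marginalizes the softmax over all sample pairs."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    v_ch, w_ch = _sbe_weights(history[chosen], t, alpha, init_value, normalize)
    v_un, w_un = _sbe_weights(history[unchosen], t, alpha, init_value, normalize)
    z = beta * (v_un[None, :] - v_ch[:, None])
    p = np.where(z >= 0, np.exp(-np.clip(z, 0, None)) / (1 + np.exp(-np.clip(z, 0, None))),
                 1.0 / (1 + np.exp(np.clip(z, None, 0))))
    return float(w_ch @ p @ w_un)


# ---------------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class ModelSpec:
    """One fittable/simulable model: a key, a step rule, and its fit space.

    The fit space is a vector of coordinates in [0, 1] (``fit_params``);
    ``to_params`` maps a vector to a ModelParams. OL2's ordering constraint
    0 < alpha2 <= alpha1 is enforced by fitting the ratio alpha2/alpha1.
    """

    key: str
    regimes: tuple[str, ...]
    fit_params_partial: tuple[str, ...]
    fit_params_complete: tuple[str, ...]
    step: object                       # (state, fb, params, regime) -> state
    kernel_id: int = -1                # id in the numba NLL kernel; -1 = python path
    uses_history: bool = False         # SBE-style sampling likelihood

    def fit_params(self, regime: str) -> tuple[str, ...]:
        return self.fit_params_partial if regime == PARTIAL else self.fit_params_complete

    def n_params(self, regime: str) -> int:
        return len(self.fit_params(regime))

    def to_params(self, vector, regime: str) -> ModelParams:
        names = self.fit_params(regime)
        if len(vector) != len(names):
            raise ValueError(f"{self.key}/{regime} expects {len(names)} params")
        kw = dict(zip(names, (float(x) for x in vector)))
        ratio = kw.pop("a2_ratio", None)
        p = ModelParams(**{k: v for k, v in kw.items()})
        if self.key == "OL1":
            p = replace(p, alpha2=p.alpha1)
        elif ratio is not None:
            p = replace(p, alpha2=ratio * p.alpha1)
        return p.validate()


def _spec(key, regimes, partial_names, complete_names, step, kernel_id,
          uses_history=False):
    return ModelSpec(key, regimes, tuple(partial_names), tuple(complete_names),
                     step, kernel_id, uses_history)


def _rp(variant):
    return lambda s, fb, p, regime: rp_step(s, fb, p, variant, regime)


MODEL_REGISTRY: dict[str, ModelSpec] = {m.key: m for m in [
    _spec("SQL", (PARTIAL, COMPLETE), ("beta", "alpha1"), ("beta", "alpha1"),
          lambda s, fb, p, r: sql_step(s, fb, p, r, extended=False), 0),
    _spec("SQLX", (COMPLETE,), (), ("beta", "alpha1", "alpha2"),
          lambda s, fb, p, r: sql_step(s, fb, p, r, extended=True), 1),
    _spec("RPD", (PARTIAL, COMPLETE), ("beta", "alpha1", "alpha2"),
          ("beta", "alpha1", "alpha2", "alpha3"), _rp("RPD"), 2),
    _spec("RPA", (PARTIAL, COMPLETE), ("beta", "alpha1", "alpha2"),
          ("beta", "alpha1", "alpha2", "alpha3"), _rp("RPA"), 3),
    _spec("RPM", (PARTIAL, COMPLETE), ("beta", "alpha1", "alpha2"),
          ("beta", "alpha1", "alpha2", "alpha3"), _rp("RPM"), 4),
    _spec("Dif", (COMPLETE,), (), ("beta", "alpha1"), dif_step, 5),
    _spec("Hyb", (PARTIAL, COMPLETE), ("beta", "alpha1", "w"),
          ("beta", "alpha1", "w"), hyb_step, 6),
    _spec("FQL", (PARTIAL, COMPLETE), ("beta", "alpha1", "alpha2"),
          ("beta", "alpha1", "alpha2"), fql_step, 7),
    _spec("EWA", (PARTIAL, COMPLETE), ("beta", "rho", "phi"),
          ("beta", "rho", "phi", "delta_imit"), ewa_step, 8),
    _spec("SBE", (PARTIAL, COMPLETE), ("beta", "alpha1"), ("beta", "alpha1"),
          sbe_append, -1, uses_history=True),
    _spec("RelAsym", (PARTIAL, COMPLETE), ("beta", "alpha1", "alpha_conf", "alpha_disc"),
          ("beta", "alpha1", "alpha_conf", "alpha_disc"), relasym_step, 9),
    _spec("OL1", (PARTIAL, COMPLETE), ("beta", "alpha1"), ("beta", "alpha1", "w"),
          ol_step, 10),
    _spec("OL2", (PARTIAL, COMPLETE), ("beta", "alpha1", "a2_ratio"),
          ("beta", "alpha1", "a2_ratio", "w"), ol_step, 11),
]}

MAIN_MODEL_SPACE = ("SQL", "RPA", "Dif", "Hyb", "OL1", "OL2")


def get_model(key: str, regime: str | None = None) -> ModelSpec:
    try:
        spec = MODEL_REGISTRY[key]
    except KeyError:
        raise KeyError(f"unknown model key {key!r}; known: {sorted(MODEL_REGISTRY)}")
    if regime is not None and regime not in spec.regimes:
        raise ConfigurationError(f"model {key} does not support regime {regime!r}")
    return spec
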