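"""Compiled trial-replay kernels for the fitting hot path.

The public per-trial step rules in :mod:`contextrl.models` are the reference
implementation; this module replays a whole learning phase in one compiled
loop so that MAP fitting and the recovery studies stay fast. The test suite
checks the two paths agree to machine precision for every family.

Parameter vectors use one canonical layout (indices below) regardless of
which subset a family reads. Missed trials are encoded as chosen = -1 and
contribute neither a likelihood term nor a state update.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .models import AgentState, ModelParams
from .task_env import STIMULI

STIM_INDEX = {s: i for i, s in enumerate(STIMULI)}
CTX_INDEX = {"A1B": 0, "A2C": 1}
CTX_OF_STIM = np.array([0, 0, 1, 1], dtype=np.int8)

# canonical parameter slots
(P_BETA, P_A1, P_A2, P_A3, P_W, P_RHO, P_PHI, P_DELTA, P_CONF, P_DISC) = range(10)

# kernel model ids (mirrors ModelSpec.kernel_id)
(M_SQL, M_SQLX, M_RPD, M_RPA, M_RPM, M_DIF, M_HYB, M_FQL, M_EWA,
 M_RELASYM, M_OL1, M_OL2) = range(12)


def params_to_vector(p: ModelParams) -> np.ndarray:
    return np.array([p.beta, p.alpha1, p.alpha2, p.alpha3, p.w, p.rho, p.phi,
                     p.delta_imit, p.alpha_conf, p.alpha_disc], dtype=np.float64)


@njit(cache=True)
def _logistic_nll(z):
    # -log sigmoid(-z) = log(1 + exp(z)), stable in both tails
    if z > 0.0:
        return z + np.log1p(np.exp(-z))
    return np.log1p(np.exp(z))


@njit(cache=True)
def replay_nll(model_id, complete, p, chosen, unchosen, r_ch, r_un, q0):
    """Negative log-likelihood of the observed learning-phase choices plus the
    end-of-learning option values. Returns (nll, q[4])."""
    q = np.full(4, q0)
    v = np.zeros(2)
    n = np.ones(4)
    nll = 0.0
    beta = p[P_BETA]
    for i in range(chosen.shape[0]):
        ch = chosen[i]
        if ch < 0:
            continue
        un = unchosen[i]
        rc = r_ch[i]
        ru = r_un[i]
        nll += _logistic_nll(beta * (q[un] - q[ch]))

        if model_id == M_SQL:
            q[ch] += p[P_A1] * (rc - q[ch])
        elif model_id == M_SQLX:
            q[ch] += p[P_A1] * (rc - q[ch])
            q[un] += p[P_A2] * (ru - q[un])
        elif model_id == M_RPD or model_id == M_RPA or model_id == M_RPM:
            cf = ru if complete else q[un]
            if model_id == M_RPD:
                rx = rc
            elif model_id == M_RPA:
                rx = 0.5 * (rc + cf)
            else:
                rx = rc if rc > cf else cf
            cx = 0 if ch < 2 else 1
            v[cx] += p[P_A1] * (rx - v[cx])
            q[ch] += p[P_A2] * ((rc - v[cx]) - q[ch])
            if complete:
                q[un] += p[P_A3] * ((ru - v[cx]) - q[un])
        elif model_id == M_DIF:
            q[ch] += p[P_A1] * ((rc - ru) - q[ch])
        elif model_id == M_HYB:
            cf = ru if complete else q[un]
            rhyb = p[P_W] * rc + (1.0 - p[P_W]) * (rc - cf)
            q[ch] += p[P_A1] * (rhyb - q[ch])
        elif model_id == M_FQL:
            q[ch] += p[P_A1] * (rc - q[ch])
            q[un] = p[P_A2] * q[un]
        elif model_id == M_EWA:
            n_ch = n[ch]
            n[ch] = p[P_RHO] * n_ch + 1.0
            q[ch] = (q[ch] * n_ch * p[P_PHI] + rc) / n[ch]
            if complete:
                n_un = n[un]
                n[un] = p[P_RHO] * n_un + 1.0
                q[un] = (q[un] * n_un * p[P_PHI] + p[P_DELTA] * ru) / n[un]
        elif model_id == M_RELASYM:
            cx = 0 if ch < 2 else 1
            v[cx] += p[P_A1] * (rc - v[cx])
            d_ch = (rc - v[cx]) - q[ch]
            q[ch] += (p[P_CONF] if d_ch > 0 else p[P_DISC]) * d_ch
            if complete:
                d_un = (ru - v[cx]) - q[un]
                q[un] += (p[P_CONF] if d_un < 0 else p[P_DISC]) * d_un
        else:  # M_OL1 / M_OL2
            if complete:
                r = p[P_W] * rc + (1.0 - p[P_W]) * (rc - ru)
            else:
                r = rc
            delta = r - q[ch]
            q[ch] += p[P_A1] * delta
            q[un] -= p[P_A2] * delta
    return nll, q


def pack_learning_trials(learning_df) -> dict[str, np.ndarray]:
    """Compact integer/float arrays for one subject's learning phase.

    ``chosen``/``unchosen`` are stimulus indices (A1,B,A2,C -> 0..3); missed
    trials get chosen = unchosen = -1 and NaN rewards.
    """
    nrow = len(learning_df)
    chosen = np.full(nrow, -1, dtype=np.int64)
    unchosen = np.full(nrow, -1, dtype=np.int64)
    r_ch = np.full(nrow, np.nan)
    r_un = np.full(nrow, np.nan)
    for k, row in enumerate(learning_df.itertuples(index=False)):
        if not isinstance(row.choice, str) or row.choice == "":
            continue
        ch = row.choice
        un = row.stim_left if row.stim_right == ch else row.stim_right
        chosen[k] = STIM_INDEX[ch]
        unchosen[k] = STIM_INDEX[un]
        r_ch[k] = row.r_chosen
        if row.r_unchosen == row.r_unchosen:  # not NaN
            r_un[k] = row.r_unchosen
    return {"chosen": chosen, "unchosen": unchosen, "r_ch": r_ch, "r_un": r_un}


def python_replay_nll(spec, params: ModelParams, packed: dict, regime: str,
                      init_q: float = 0.0):
    """Reference replay through the public step rules (used for SBE and as the
    slow path); same contract as :func:`replay_nll`."""
    from .models import Feedback, sbe_trial_likelihood, softmax_log_prob

    state = AgentState.fresh(init_q)
    labels = STIMULI
    nll = 0.0
    for k in range(len(packed["chosen"])):
        state.t += 1
        ch = packed["chosen"][k]
        if ch < 0:
            continue
        un = packed["unchosen"][k]
        s_ch, s_un = labels[ch], labels[un]
        if spec.uses_history:
            pr = sbe_trial_likelihood(state.history, state.t, s_ch, s_un,
                                      params.alpha1, params.beta, init_value=init_q)
            nll -= np.log(pr)
        else:
            nll -= softmax_log_prob(state.q[s_ch], state.q[s_un], params.beta)
        ru = packed["r_un"][k]
        fb = Feedback(s_ch, s_un, packed["r_ch"][k],
                      None if ru != ru else float(ru))
        spec.step(state, fb, params, regime)
    q = np.array([state.q[s] for s in labels])
    return nll, q, state
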