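"""Step rules, likelihoods, degeneracies, and the two-route oracle check."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from contextrl.models import (MODEL_REGISTRY, AgentState, ConfigurationError,
                              Feedback, ModelParams, dif_step, ewa_step,
                              fql_step, get_model, hyb_step, hybrid_reward,
                              ol_step, rp_step, sbe_trial_likelihood,
                              softmax_choice_prob, sql_step)
from contextrl.task_env import COMPLETE, PARTIAL, STIMULI


def state_with(q, **kw):
    s = AgentState.fresh(0.0)
    s.q.update(q)
    for k, v in kw.items():
        getattr(s, k).update(v)
    return s


class TestSoftmax:
    def test_hand_evaluated_logistic(self):
        # beta=0.1, values 15 vs 5: 1/(1+e^-1)
        assert softmax_choice_prob(15.0, 5.0, 0.1) == pytest.approx(
            1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)

    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3), st.floats(0, 10))
    @settings(max_examples=200, deadline=None)
    def test_probabilities_complement(self, qa, qb, beta):
        pa = softmax_choice_prob(qa, qb, beta)
        pb = softmax_choice_prob(qb, qa, beta)
        assert 0.0 < pa < 1.0 or qa != qb
        assert pa + pb == pytest.approx(1.0, abs=1e-12)

    def test_indifference_limits(self):
        assert softmax_choice_prob(50.0, 50.0, 3.0) == 0.5
        assert softmax_choice_prob(90.0, 10.0, 0.0) == 0.5

    def test_extreme_gap_is_stable(self):
        assert softmax_choice_prob(1e4, -1e4, 10.0) == pytest.approx(1.0)
        assert softmax_choice_prob(-1e4, 1e4, 10.0) == pytest.approx(0.0, abs=1e-300)


class TestSingleSteps:
    """Hand-computed one-step examples for each family."""

    def test_sql_partial_update(self):
        s = state_with({"A1": 50.0})
        sql_step(s, Feedback("A1", "B", 64.0), ModelParams(alpha1=0.25), PARTIAL)
        assert s.q["A1"] == pytest.approx(53.5)
        assert s.q["B"] == 0.0

    @pytest.mark.parametrize("alpha,expected", [(1.0, 64.0), (0.0, 50.0)])
    def test_sql_rate_limits(self, alpha, expected):
        s = state_with({"A1": 50.0})
        sql_step(s, Feedback("A1", "B", 64.0), ModelParams(alpha1=alpha), PARTIAL)
        assert s.q["A1"] == expected

    def test_extended_sql_requires_complete(self):
        with pytest.raises(ConfigurationError):
            sql_step(AgentState.fresh(), Feedback("A1", "B", 64.0),
                     ModelParams(), PARTIAL, extended=True)

    def test_rpa_partial_averages_with_unchosen_value(self):
        s = state_with({"B": 44.0})
        p = ModelParams(alpha1=1.0, alpha2=0.0)
        rp_step(s, Feedback("A1", "B", 64.0), p, "RPA", PARTIAL)
        assert s.v["A1B"] == pytest.approx((64.0 + 44.0) / 2)

    def test_rpd_full_rate_sequence(self):
        # V updates first; the chosen prediction error then sees the new V
        s = state_with({"A1": 10.0})
        p = ModelParams(alpha1=1.0, alpha2=1.0)
        rp_step(s, Feedback("A1", "B", 64.0), p, "RPD", PARTIAL)
        assert s.v["A1B"] == 64.0
        assert s.q["A1"] == pytest.approx((64.0 - 64.0))  # -> r - V = 0

    def test_dif_learns_outcome_difference(self):
        s = AgentState.fresh()
        dif_step(s, Feedback("A1", "B", 64.0, 54.0), ModelParams(alpha1=0.5),
                 COMPLETE)
        assert s.q["A1"] == pytest.approx(5.0)
        with pytest.raises(ConfigurationError):
            dif_step(s, Feedback("A1", "B", 64.0), ModelParams(), PARTIAL)

    @pytest.mark.parametrize("w,expected", [(1.0, 64.0), (0.0, 10.0), (0.5, 37.0)])
    def test_hybrid_reward_mixture(self, w, expected):
        assert hybrid_reward(64.0, 54.0, w) == pytest.approx(expected)

    def test_fql_unchosen_decay(self):
        s = state_with({"B": 40.0})
        fql_step(s, Feedback("A1", "B", 64.0), ModelParams(alpha1=0.3, alpha2=0.9),
                 PARTIAL)
        assert s.q["B"] == pytest.approx(36.0)

    def test_ewa_hand_case(self):
        # N=1, rho=1, phi=1: N'=2, Q = (50*1*1 + 64)/2 = 57
        s = state_with({"A1": 50.0})
        ewa_step(s, Feedback("A1", "B", 64.0),
                 ModelParams(rho=1.0, phi=1.0), PARTIAL)
        assert s.n["A1"] == 2.0
        assert s.q["A1"] == pytest.approx(57.0)

    def test_ewa_degenerate_jumps_to_reward(self):
        s = state_with({"A1": 50.0})
        ewa_step(s, Feedback("A1", "B", 64.0), ModelParams(rho=0.0, phi=0.0),
                 PARTIAL)
        assert s.q["A1"] == 64.0

    def test_ol_moves_values_apart(self):
        s = state_with({"A1": 50.0, "B": 50.0})
        ol_step(s, Feedback("A1", "B", 64.0),
                ModelParams(alpha1=0.2, alpha2=0.2), PARTIAL)
        assert s.q["A1"] == pytest.approx(52.8)
        assert s.q["B"] == pytest.approx(47.2)
        assert s.q["A2"] == 0.0 and s.q["C"] == 0.0  # other context frozen

    def test_relasym_branch_selection(self):
        # positive chosen PE takes the confirmatory rate
        s = state_with({"A1": 0.0})
        p = ModelParams(alpha1=0.0, alpha_conf=0.3, alpha_disc=0.1)
        rpref = Feedback("A1", "B", 10.0)
        from contextrl.models import relasym_step
        relasym_step(s, rpref, p, PARTIAL)
        assert s.q["A1"] == pytest.approx(0.3 * 10.0)
        # negative unchosen PE is also confirmatory (flipped sign rule)
        s2 = state_with({"A1": 0.0, "B": 0.0})
        relasym_step(s2, Feedback("A1", "B", 0.0, -4.0), p, COMPLETE)
        assert s2.q["B"] == pytest.approx(0.3 * -4.0)


class TestSBE:
    def test_recency_weight_of_most_recent_sample(self):
        # one sample at t-1, alpha 0.5: raw weight 0.25, sole sample -> prob 1
        hist = {"A1": [(4, 60.0)], "B": []}
        p = sbe_trial_likelihood(hist, 5, "A1", "B", alpha=0.5, beta=0.0)
        assert p == 0.5  # beta=0 -> indifference regardless of weights

    def test_empty_histories_give_chance(self):
        hist = {s: [] for s in STIMULI}
        assert sbe_trial_likelihood(hist, 3, "A1", "B", 0.5, 2.0) == 0.5

    def test_matches_oracle_double_sum(self, rng):
        hist = {"A1": [(1, 60.0), (3, 70.0), (6, 40.0)], "B": [(2, 55.0), (5, 52.0)]}
        ohist = [hist["A1"], hist["B"], [], []]
        for beta in (0.0, 0.05, 0.3):
            mine = sbe_trial_likelihood(hist, 8, "A1", "B", 0.3, beta)
            ref = oracles.sbe_prob(ohist, 8, 0, 1, 0.3, beta)
            assert mine == pytest.approx(ref, rel=1e-12)

    def test_future_sample_rejected(self):
        hist = {"A1": [(9, 60.0)], "B": []}
        with pytest.raises(IndexError):
            sbe_trial_likelihood(hist, 5, "A1", "B", 0.5, 0.1)


@pytest.mark.parametrize("key,regime", [
    (k, r) for k in sorted(MODEL_REGISTRY) for r in MODEL_REGISTRY[k].regimes
])
def test_step_rules_match_independent_oracle(key, regime, rng):
    """Two-route check: package step rules vs the literal transcription of the
    update equations, on random (state, feedback, params) sequences."""
    spec = MODEL_REGISTRY[key]
    for rep in range(25):
        trials = oracles.random_trials(rng, 40, regime == COMPLETE)
        op = oracles.random_params(rng)
        if key == "OL1":
            op["alpha2"] = op["alpha1"]
        elif key == "OL2":
            # the model's own constraint: 0 < alpha2 <= alpha1
            op["alpha2"] = op["alpha2"] * op["alpha1"]
        params = ModelParams(**{k: v for k, v in op.items()})
        onll, oq = oracles.replay(key, trials, op, regime == COMPLETE)
        state = AgentState.fresh(0.0)
        nll = 0.0
        from contextrl.models import softmax_choice_prob as smax
        for ch, un, rc, ru in trials:
            state.t += 1
            if ch < 0:
                continue
            sch, sun = STIMULI[ch], STIMULI[un]
            if spec.uses_history:
                pr = sbe_trial_likelihood(state.history, state.t, sch, sun,
                                          params.alpha1, params.beta)
            else:
                pr = smax(state.q[sch], state.q[sun], params.beta)
            nll -= math.log(pr)
            fb = Feedback(sch, sun, rc, None if ru != ru else ru)
            spec.step(state, fb, params, regime)
        q = np.array([state.q[s] for s in STIMULI])
        assert nll == pytest.approx(onll, rel=1e-12, abs=1e-12)
        np.testing.assert_allclose(q, oq, rtol=1e-12, atol=1e-12)


class TestDegeneracyLattice:
    """Parameter settings under which richer families collapse exactly."""

    def _traj(self, key, params, regime, seed=5):
        rng = np.random.default_rng(seed)
        spec = MODEL_REGISTRY[key]
        state = AgentState.fresh(0.0)
        out = []
        trials = oracles.random_trials(rng, 60, regime == COMPLETE, missed_rate=0)
        for ch, un, rc, ru in trials:
            state.t += 1
            fb = Feedback(STIMULI[ch], STIMULI[un], rc, None if ru != ru else ru)
            spec.step(state, fb, params, regime)
            out.append([state.q[s] for s in STIMULI])
        return np.array(out)

    def test_hyb_w1_equals_sql(self):
        a = self._traj("Hyb", ModelParams(alpha1=0.3, w=1.0), PARTIAL)
        b = self._traj("SQL", ModelParams(alpha1=0.3), PARTIAL)
        np.testing.assert_array_equal(a, b)

    def test_hyb_w0_complete_equals_dif(self):
        a = self._traj("Hyb", ModelParams(alpha1=0.3, w=0.0), COMPLETE)
        b = self._traj("Dif", ModelParams(alpha1=0.3), COMPLETE)
        np.testing.assert_array_equal(a, b)

    def test_ol_alpha2_zero_equals_sql(self):
        a = self._traj("OL2", ModelParams(alpha1=0.3, alpha2=0.0), PARTIAL)
        b = self._traj("SQL", ModelParams(alpha1=0.3), PARTIAL)
        np.testing.assert_array_equal(a, b)

    def test_fql_alpha2_one_equals_sql(self):
        a = self._traj("FQL", ModelParams(alpha1=0.3, alpha2=1.0), PARTIAL)
        b = self._traj("SQL", ModelParams(alpha1=0.3), PARTIAL)
        np.testing.assert_array_equal(a, b)

    def test_relasym_symmetric_equals_rp(self):
        p = ModelParams(alpha1=0.2, alpha2=0.35, alpha_conf=0.35, alpha_disc=0.35)
        a = self._traj("RelAsym", p, PARTIAL)
        b = self._traj("RPD", p, PARTIAL)
        np.testing.assert_allclose(a, b, rtol=1e-12)


def test_ol1_conserves_context_sums(rng):
    """With equal rates the chosen and unchosen increments cancel, so the sum
    of each context pair's values never moves from its initial value."""
    params = ModelParams(alpha1=0.37, alpha2=0.37)
    for init in (0.0, 50.0):
        state = AgentState.fresh(init)
        for ch, un, rc, ru in oracles.random_trials(rng, 200, False, missed_rate=0):
            fb = Feedback(STIMULI[ch], STIMULI[un], rc)
            ol_step(state, fb, params, PARTIAL)
            assert state.q["A1"] + state.q["B"] == pytest.approx(2 * init, abs=1e-9)
            assert state.q["A2"] + state.q["C"] == pytest.approx(2 * init, abs=1e-9)


def test_extended_ol_reduces_to_simple_ol():
    """Under complete feedback with hybrid reward, the extended model equals a
    simple opposing learner on transformed means mu1' = mu1 - (1-w)*mu2 (and
    symmetrically), with reward SD scaled by sqrt(1 + (1-w)^2): matching
    choice frequencies confirm the reduction."""
    mu1, mu2, w, a, beta = 7.0, 5.0, 0.6, 0.2, 0.1
    n_runs, n_trials = 400, 1500

    def sim_extended(seed):
        rng = np.random.default_rng(seed)
        q = np.zeros((n_runs, 2))
        wins = 0.0
        for _ in range(n_trials):
            z = beta * (q[:, 1] - q[:, 0])
            ch = (rng.random(n_runs) >= 1 / (1 + np.exp(z))).astype(int)
            r_ch = rng.normal(np.where(ch == 0, mu1, mu2), 1.0)
            r_un = rng.normal(np.where(ch == 0, mu2, mu1), 1.0)
            d = (w * r_ch + (1 - w) * (r_ch - r_un)) - q[np.arange(n_runs), ch]
            q[np.arange(n_runs), ch] += a * d
            q[np.arange(n_runs), 1 - ch] -= a * d
            wins += (ch == 0).mean()
        return wins / n_trials

    from contextrl.synthetic_data import _simulate_ol_pair
    s = math.sqrt(1 + (1 - w) ** 2)
    m1p, m2p = mu1 - (1 - w) * mu2, mu2 - (1 - w) * mu1
    ch, _ = _simulate_ol_pair(a, a, beta * s, (m1p / s, m2p / s),
                              n_trials, n_runs, np.random.default_rng(91))
    simple = (ch == 0).mean()
    ext = sim_extended(90)
    assert ext == pytest.approx(simple, abs=0.02)
    # the additive (plus-sign) transform does not reproduce the behavior
    m1pp, m2pp = mu1 + (1 - w) * mu2, mu2 + (1 - w) * mu1
    ch, _ = _simulate_ol_pair(a, a, beta * s, (m1pp / s, m2pp / s),
                              n_trials, n_runs, np.random.default_rng(92))
    assert abs((ch == 0).mean() - ext) > 0.005


def test_registry_fit_spaces():
    assert get_model("OL1").to_params([0.1, 0.3], PARTIAL).alpha2 == 0.3
    p = get_model("OL2").to_params([0.1, 0.4, 0.5], PARTIAL)
    assert p.alpha2 == pytest.approx(0.2)  # ratio * alpha1 keeps alpha2 <= alpha1
    with pytest.raises(ConfigurationError):
        get_model("Dif", PARTIAL)
    with pytest.raises(KeyError):
        get_model("nope")
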