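import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bartfnirs import models as m
from bartfnirs import _fastlik as fl
from conftest import make_dataset, make_trial
from oracles import enumerate_outcomes, straight_line_subject_loglik


def state_with(p_burst=0.1, **counts):
    return m.BeliefState(p_burst=p_burst, **counts)


class TestRFPMBelief:
    def test_empty_history_gives_prior_burst_belief(self):
        params = m.RFPMParams(phi=0.9, eta=0.05, gamma=1.0, tau=1.0)
        st0 = m.initial_belief(params)
        assert st0.p_burst == pytest.approx(0.1)
        assert m.rfpm_update_belief(st0, params).p_burst == pytest.approx(0.1)

    def test_hand_evaluated_closed_form(self):
        params = m.RFPMParams(phi=0.9, eta=0.05, gamma=1.0, tau=1.0)
        st0 = state_with(cum_pumps=25, cum_successes=20)
        # 1 - (0.9 + 0.05*20) / (1 + 0.05*25) = 1 - 1.9/2.25
        assert m.rfpm_update_belief(st0, params).p_burst == pytest.approx(1 - 1.9 / 2.25)

    def test_large_eta_limit_approaches_success_frequency(self):
        params = m.RFPMParams(phi=0.9, eta=1e9, gamma=1.0, tau=1.0)
        st0 = state_with(cum_pumps=100, cum_successes=80)
        assert m.rfpm_update_belief(st0, params).p_burst == pytest.approx(0.2, abs=1e-6)

    def test_belief_converges_to_observed_frequency_under_repeats(self):
        params = m.RFPMParams(phi=0.5, eta=0.1, gamma=1.0, tau=1.0)
        state = m.initial_belief(params)
        for _ in range(200):  # explosion-free trials of 10 pumps
            state = m.rfpm_update_belief(m.observe_trial(state, 10, False), params)
        assert state.p_burst == pytest.approx(0.0, abs=0.01)


class TestRFPMChoice:
    def test_unit_hazard_gives_v_equal_gamma(self):
        params = m.RFPMParams(phi=0.5, eta=0.1, gamma=1.2, tau=1.0)
        assert m.rfpm_optimal_pumps(1 - math.exp(-1), params) == pytest.approx(1.2)

    def test_gamma_zero_never_pumps(self):
        params = m.RFPMParams(phi=0.5, eta=0.1, gamma=0.0, tau=1.0)
        for p in (0.01, 0.5, 0.99):
            assert m.rfpm_optimal_pumps(p, params) == 0.0

    def test_hand_evaluated_target(self):
        params = m.RFPMParams(phi=0.5, eta=0.1, gamma=1.2, tau=1.0)
        assert m.rfpm_optimal_pumps(0.1, params) == pytest.approx(1.2 / 0.1053605, rel=1e-5)

    def test_printed_dialect_increases_with_burst_belief(self):
        params = m.RFPMParams(phi=0.5, eta=0.1, gamma=1.2, tau=1.0)
        printed = m.ModelDialects(optimal_pumps="printed")
        v = [m.rfpm_optimal_pumps(p, params, printed) for p in (0.1, 0.3, 0.6)]
        assert v[0] < v[1] < v[2]
        v_def = [m.rfpm_optimal_pumps(p, params) for p in (0.1, 0.3, 0.6)]
        assert v_def[0] > v_def[1] > v_def[2]

    def test_pump_prob_half_at_target_any_temperature(self):
        for tau in (0.0, 0.7, 5.0):
            params = m.RFPMParams(phi=0.5, eta=0.1, gamma=1.0, tau=tau)
            assert m.rfpm_pump_prob(4.5, 4.5, params) == pytest.approx(0.5)

    def test_tau_zero_is_coin_flip_everywhere(self):
        params = m.RFPMParams(phi=0.5, eta=0.1, gamma=1.0, tau=0.0)
        assert m.rfpm_pump_prob(100.0, 2.0, params) == pytest.approx(0.5)

    def test_hand_evaluated_logistic(self):
        params = m.RFPMParams(phi=0.5, eta=0.1, gamma=1.0, tau=2.0)
        assert m.rfpm_pump_prob(6, 5.0, params) == pytest.approx(1 / (1 + math.e**2))

    @given(st.floats(0.01, 0.99), st.integers(1, 100))
    @settings(deadline=None, max_examples=50)
    def test_pump_prob_non_increasing_in_l(self, p_burst, l):
        params = m.RFPMParams(phi=0.5, eta=0.1, gamma=1.5, tau=1.3)
        v = m.rfpm_optimal_pumps(p_burst, params)
        assert m.rfpm_pump_prob(l + 1, v, params) <= m.rfpm_pump_prob(l, v, params)


class TestEWMVMBelief:
    def test_no_history_gives_prior(self):
        params = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.0, tau=1.0, lam=1.5)
        st0 = m.initial_belief(params)
        assert m.ewmvm_update_belief(st0, params).p_burst == pytest.approx(0.1)

    def test_eta_zero_pins_belief_at_prior(self):
        params = m.EWMVMParams(phi=0.9, eta=1e-300, gamma=0.0, tau=1.0, lam=1.5)
        state = m.initial_belief(params)
        for _ in range(20):  # observed burst rate 1/4 != the 0.1 prior
            state = m.ewmvm_update_belief(m.observe_trial(state, 4, True), params)
        assert state.p_burst == pytest.approx(0.1, abs=1e-9)

    def test_hand_evaluated_blend(self):
        # w = 1/(1 + 0.05*40) = 1/3; observed rate 4/40 = 0.1; prior 0.1
        params = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.0, tau=1.0, lam=1.5)
        st0 = state_with(cum_pumps=40, cum_explosions=4)
        assert m.ewmvm_update_belief(st0, params).p_burst == pytest.approx(
            (1 / 3) * 0.1 + (2 / 3) * 0.1
        )

    def test_belief_converges_to_observed_rate(self):
        params = m.EWMVMParams(phi=0.99, eta=0.1, gamma=0.0, tau=1.0, lam=1.5)
        state = m.initial_belief(params)
        for _ in range(300):  # every fifth pump bursts: rate 0.2 per pump
            state = m.ewmvm_update_belief(m.observe_trial(state, 5, True), params)
        assert state.p_burst == pytest.approx(0.2, abs=0.01)

    def test_cumulative_trial_rate_dialect(self):
        params = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.0, tau=1.0, lam=1.5)
        dial = m.ModelDialects(observed_rate="cumulative")
        st0 = state_with(cum_pumps=40, cum_explosions=4, n_trials_seen=8)
        w = 1 / 3
        assert m.ewmvm_update_belief(st0, params, dial).p_burst == pytest.approx(
            w * 0.1 + (1 - w) * 0.5
        )


class TestEWMVMUtility:
    def test_first_pump_no_stake_no_variance(self):
        params = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.0, tau=1.0, lam=2.0)
        assert m.ewmvm_utility(1, 0.3, params) == pytest.approx(0.7)

    def test_certain_success_is_full_reward(self):
        params = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.3, tau=1.0, lam=2.0)
        for l in (1, 5, 20):
            assert m.ewmvm_utility(l, 0.0, params, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_hand_evaluated_utility(self):
        params = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.05, tau=1.0, lam=2.0)
        # 0.9 - 0.1*2*4 + 0.05*0.1*0.9*(1+8)^2
        assert m.ewmvm_utility(5, 0.1, params, 1.0) == pytest.approx(0.4645)

    def test_printed_loss_weight_dialect(self):
        params = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.0, tau=1.0, lam=2.0)
        printed = m.ModelDialects(loss_weight="printed")
        # loss term weighted by (1-p): 0.9 - 0.9*2*4 = -6.3
        assert m.ewmvm_utility(5, 0.1, params, 1.0, printed) == pytest.approx(-6.3)

    def test_softmax_midpoint_and_temperature(self):
        params = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.0, tau=5.32, lam=2.0)
        assert m.ewmvm_pump_prob(0.0, params) == pytest.approx(0.5)
        zero_tau = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.0, tau=0.0, lam=2.0)
        assert m.ewmvm_pump_prob(123.0, zero_tau) == pytest.approx(0.5)
        assert m.ewmvm_pump_prob(0.2, params) == pytest.approx(
            1 / (1 + math.exp(-1.064)), rel=1e-6
        )

    @given(st.floats(-3.0, 3.0), st.floats(-3.0, 3.0))
    @settings(deadline=None, max_examples=50)
    def test_pump_prob_increasing_in_utility(self, u1, u2):
        params = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.0, tau=1.7, lam=2.0)
        lo, hi = sorted((u1, u2))
        assert m.ewmvm_pump_prob(lo, params) <= m.ewmvm_pump_prob(hi, params)


class TestTrialLoglik:
    def test_tau_zero_cashout_counts_stop_decision(self):
        params = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.0, tau=0.0, lam=2.0)
        trial = make_trial(3, False)
        ll = m.trial_loglik(trial, m.initial_belief(params), params)
        assert ll == pytest.approx(4 * math.log(0.5))

    def test_tau_zero_explosion_censors_stop_decision(self):
        params = m.EWMVMParams(phi=0.9, eta=0.05, gamma=0.0, tau=0.0, lam=2.0)
        trial = make_trial(3, True)
        ll = m.trial_loglik(trial, m.initial_belief(params), params)
        assert ll == pytest.approx(3 * math.log(0.5))

    def test_zero_pump_cashout_single_stop_term(self):
        params = m.RFPMParams(phi=0.9, eta=0.05, gamma=0.5, tau=0.0)
        trial = make_trial(0, False)
        ll = m.trial_loglik(trial, m.initial_belief(params), params)
        assert ll == pytest.approx(math.log(0.5))

    @pytest.mark.parametrize("model", ["RFPM", "EWMVM"])
    @pytest.mark.parametrize("max_pumps", [2, 3, 4])
    def test_outcome_tree_normalizes_to_one(self, model, max_pumps):
        """exp(log-likelihood), weighted by the uniform explosion mechanism,
        must sum to exactly 1 over the enumerated outcome tree."""
        rng = np.random.default_rng(2024)
        for _ in range(8):
            if model == "RFPM":
                params = m.RFPMParams(
                    phi=rng.uniform(0.1, 0.95), eta=rng.uniform(0.001, 1.0),
                    gamma=rng.uniform(0.0, 3.0), tau=rng.uniform(0.0, 8.0),
                )
            else:
                params = m.EWMVMParams(
                    phi=rng.uniform(0.1, 0.95), eta=rng.uniform(0.001, 1.0),
                    gamma=rng.uniform(-0.2, 0.2), tau=rng.uniform(0.0, 8.0),
                    lam=rng.uniform(0.5, 4.0),
                )
            state = m.initial_belief(params)
            total = 0.0
            for n, exploded, p_choice, p_joint in enumerate_outcomes(params, max_pumps):
                trial = make_trial(
                    n, exploded, max_pumps=max_pumps,
                    explosion_point=n if exploded else max_pumps,
                )
                ll = m.trial_loglik(trial, state, params)
                assert math.exp(ll) == pytest.approx(p_choice, abs=1e-10)
                total += p_joint
            assert total == pytest.approx(1.0, abs=1e-10)


class TestSubjectLoglik:
    def test_single_trial_equals_trial_loglik(self, ewmvm_params):
        d = make_dataset([(4, False)])
        total, per = m.subject_loglik(d, ewmvm_params)
        expected = m.trial_loglik(
            d.trials[0], m.initial_belief(ewmvm_params), ewmvm_params
        )
        assert total == pytest.approx(expected)
        assert per.shape == (1,)

    def test_belief_threading_differs_from_naive_restart(self, ewmvm_params):
        first = [(4, False), (5, True), (3, False)]
        second = [(6, False), (2, True), (4, False)]
        full = make_dataset(first + second)
        total_full, _ = m.subject_loglik(full, ewmvm_params)
        naive = (
            m.subject_loglik(make_dataset(first), ewmvm_params)[0]
            + m.subject_loglik(make_dataset(second), ewmvm_params)[0]
        )
        assert total_full != pytest.approx(naive)

    @pytest.mark.parametrize("model", ["RFPM", "EWMVM"])
    def test_matches_straight_line_reimplementation(self, model, default_task):
        from bartfnirs import synthetic_data as sd

        if model == "RFPM":
            params = m.RFPMParams(phi=0.95, eta=0.03, gamma=0.5, tau=4.0)
        else:
            params = m.EWMVMParams(phi=0.95, eta=0.03, gamma=0.01, tau=4.0, lam=2.0)
        d = sd.simulate_subject(params, default_task, rng=11)
        total, per = m.subject_loglik(d, params)
        assert total == pytest.approx(per.sum())
        assert total == pytest.approx(straight_line_subject_loglik(d, params), abs=1e-9)

    def test_unordered_trials_rejected(self, ewmvm_params):
        d = make_dataset([(3, False), (4, False)])
        d.trials = d.trials[::-1]  # bypass constructor validation
        with pytest.raises(ValueError, match="ordered"):
            m.subject_loglik(d, ewmvm_params)


class TestFastPathAgreement:
    """The numba kernels must agree with the readable reference to double
    precision, for both models and every dialect combination."""

    @pytest.mark.parametrize("model", ["RFPM", "EWMVM"])
    @pytest.mark.parametrize(
        "dialects",
        [
            m.ModelDialects(),
            m.ModelDialects(optimal_pumps="printed", loss_weight="printed",
                            observed_rate="cumulative"),
        ],
    )
    def test_cohort_pointwise_matches_reference(self, model, dialects, small_cohort):
        task, datasets, truth = small_cohort
        if model == "RFPM":
            params = m.RFPMParams(phi=0.95, eta=0.03, gamma=0.5, tau=4.0)
        else:
            params = m.EWMVMParams(phi=0.95, eta=0.03, gamma=0.01, tau=4.0, lam=2.0)
        names = m.param_names(model)
        theta = np.tile([getattr(params, n) for n in names], (len(datasets), 1))
        total, pw = fl.cohort_pointwise(fl.pack_cohort(datasets), theta, model, dialects)
        ref = np.concatenate(
            [m.subject_loglik(d, params, dialects=dialects)[1] for d in datasets]
        )
        np.testing.assert_allclose(pw, ref, rtol=1e-12, atol=1e-12)
        assert total == pytest.approx(ref.sum())


def test_parameter_bounds_enforced_at_construction():
    with pytest.raises(ValueError):
        m.RFPMParams(phi=1.0, eta=0.1, gamma=1.0, tau=1.0)
    with pytest.raises(ValueError):
        m.RFPMParams(phi=0.5, eta=0.0, gamma=1.0, tau=1.0)
    with pytest.raises(ValueError):
        m.RFPMParams(phi=0.5, eta=0.1, gamma=-0.1, tau=1.0)
    with pytest.raises(ValueError):
        m.EWMVMParams(phi=0.5, eta=0.1, gamma=0.0, tau=1.0, lam=0.0)
    # EWMVM gamma may be negative (signed risk preference)
    m.EWMVMParams(phi=0.5, eta=0.1, gamma=-0.5, tau=1.0, lam=1.0)
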