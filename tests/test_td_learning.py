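import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_toy_space
from posmtd import belief_inference as bi
from posmtd import td_learning as td
from posmtd.errors import (ConfigurationError, DegenerateInputError,
                           InvalidModelError)
from posmtd.state_spaces import (apply_model2_lesion, build_model1,
                                 build_model2, gaussian_dwell_kernel)


@pytest.fixture
def toy_agent():
    space = make_toy_space(0, n_states=4, n_symbols=3, n_dwell=3)
    return td.AgentState(space, params=td.LearningParams())


class TestFiringConversion:
    def test_parameter_echo(self):
        fp = td.FiringParams()
        assert td.firing_rate_from_pe(fp, 0.0) == 3.0
        assert td.firing_rate_from_pe(fp, 1.0) == 8.0
        assert td.firing_rate_from_pe(fp, -0.5) == 2.0

    def test_floor_at_zero_hz(self):
        assert td.firing_rate_from_pe(td.FiringParams(), -5.0) == 0.0

    def test_printed_k2_form_raises_firing_on_negative_error(self):
        fp = td.FiringParams(printed_k2_form=True)
        assert td.firing_rate_from_pe(fp, -0.5) == 4.0

    def test_invalid_params(self):
        with pytest.raises(ConfigurationError):
            td.FiringParams(baseline=0.0)


class TestSuccessorValue:
    def test_single_and_symmetric_successors(self, toy_agent):
        space = toy_agent.space
        # single successor
        toy_agent.T[0] = 0.0
        toy_agent.T[0, 1] = 1.0
        toy_agent.V[:] = [0.0, 0.7, 0.0, 0.0]
        assert td.successor_value_expectation(
            space, toy_agent, 0, 0) == pytest.approx(0.7)
        # two equiprobable successors with values 0 and 1 and equal
        # emission probabilities average to 0.5
        space2 = dataclasses.replace(space, O=np.tile(space.O[1], (4, 1)))
        agent2 = td.AgentState(space2)
        agent2.T[0] = 0.0
        agent2.T[0, 1] = agent2.T[0, 2] = 0.5
        agent2.V[:] = [0.0, 0.0, 1.0, 0.0]
        assert td.successor_value_expectation(
            space2, agent2, 0, 0) == pytest.approx(0.5)

    def test_weighted_average_oracle(self):
        rng = np.random.default_rng(1)
        for i in range(20):
            space = make_toy_space(50 + i, n_states=4)
            agent = td.AgentState(space)
            agent.V[:] = rng.normal(size=4)
            s, o = int(rng.integers(4)), int(rng.integers(2))
            w = agent.T[s] * space.O[:, o]
            expected = float(np.dot(w, agent.V)) / w.sum()
            assert td.successor_value_expectation(
                space, agent, s, o) == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator(self, toy_agent):
        toy_agent.T[0] = 0.0
        toy_agent.T[0, 1] = 1.0
        view = toy_agent.space_view()
        view.O[1, :] = 0.0
        with pytest.raises(DegenerateInputError):
            td.successor_value_expectation(toy_agent.space, toy_agent, 0, 0)


class TestPredictionError:
    def test_undiscounted_surprise_reward(self):
        """beta = 1, r = 1, all values 0, dwell of one step -> delta close to
        g(1) * 1 (the single-step discount)."""
        space = make_toy_space(0, deterministic=True, point_dwell=True)
        agent = td.AgentState(space)
        trace = bi.filter_sequence(space, ["o0"])
        rec = td.prediction_error(space, agent, trace, 1.0, "o1")
        g = np.exp(-agent.params.tau * 1.0)
        assert rec.total_delta == pytest.approx(g, abs=1e-12)

    def test_closed_form_discounting(self):
        """E[d] = 10 steps, tau = 0.05 -> discount exp(-0.5)."""
        space = make_toy_space(0, deterministic=True, n_dwell=10)
        D = np.zeros_like(space.D)
        D[:, 9] = 1.0
        space = dataclasses.replace(space, D=D)
        agent = td.AgentState(space)
        obs = ["o0"] + ["null"] * 9
        trace = bi.filter_sequence(space, obs)
        rec = td.prediction_error(space, agent, trace, 1.0, "o1")
        assert rec.total_delta == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_total_equals_sum_of_per_state(self):
        rng = np.random.default_rng(2)
        space = make_toy_space(11)
        agent = td.AgentState(space)
        agent.V[:] = rng.normal(size=space.n_states)
        trace = bi.filter_sequence(space, [space.alphabet.symbols[0], "null"])
        rec = td.prediction_error(space, agent, trace, 0.5, "null")
        assert rec.total_delta == pytest.approx(rec.per_state_delta.sum(),
                                                abs=1e-12)
        # gated by beta: zero posterior -> zero contribution
        beta = bi.transition_posterior(space, trace, "null")
        assert np.all(rec.per_state_delta[beta == 0] == 0)


class TestValueAndEligibility:
    def test_value_update_arithmetic(self, toy_agent):
        toy_agent.E[:] = 1.0
        td.update_values(toy_agent, 1.0)
        np.testing.assert_allclose(toy_agent.V, 0.5)
        toy_agent.E[:] = 0.0
        td.update_values(toy_agent, 1.0)
        np.testing.assert_allclose(toy_agent.V, 0.5)
        td.update_values(toy_agent, 0.0)
        np.testing.assert_allclose(toy_agent.V, 0.5)

    def test_eligibility_max_rule(self, toy_agent):
        toy_agent.E[:] = 0.8
        td.update_eligibility(toy_agent, np.zeros(4))
        np.testing.assert_allclose(toy_agent.E, 0.76)
        td.update_eligibility(toy_agent, np.ones(4))
        np.testing.assert_allclose(toy_agent.E, 1.0)
        toy_agent.E[:] = 0.0
        td.update_eligibility(toy_agent, np.zeros(4))
        np.testing.assert_allclose(toy_agent.E, 0.0)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(1, 40), st.floats(0.01, 1.0))
    def test_eligibility_decays_geometrically(self, k, e0):
        space = make_toy_space(0)
        agent = td.AgentState(space, params=td.LearningParams(gamma=0.95))
        agent.E[:] = e0
        for _ in range(k):
            td.update_eligibility(agent, np.zeros(space.n_states))
        np.testing.assert_allclose(agent.E, e0 * 0.95 ** k, rtol=1e-9)


class TestDwellLearning:
    def test_full_replacement_limit(self, task_config):
        space = build_model1(task_config)
        agent = td.AgentState(space, params=td.LearningParams(eta_d=1.0))
        td.update_dwell_distribution(agent, "left_well", 30, 1.0)
        K = gaussian_dwell_kernel(30, space.kernel)
        np.testing.assert_allclose(agent.D[space.index("left_well")], K,
                                   atol=1e-12)

    def test_zero_evidence_leaves_dwell(self, task_config):
        space = build_model1(task_config)
        agent = td.AgentState(space)
        before = agent.D.copy()
        td.update_dwell_distribution(agent, "left_well", 30, 0.0)
        np.testing.assert_allclose(agent.D, before)

    def test_sums_to_one_after_every_update(self, task_config):
        space = build_model1(task_config)
        agent = td.AgentState(space)
        rng = np.random.default_rng(0)
        for _ in range(50):
            td.update_dwell_distributions(agent, int(rng.integers(1, 120)),
                                          rng.random(space.n_states))
            np.testing.assert_allclose(agent.D.sum(axis=1), 1.0, atol=1e-9)
            assert agent.D.min() >= space.kernel.d_b - 1e-12

    def test_repeated_exposure_recovers_duration(self, task_config):
        """500 exposures to d* = 3 s pull the dwell mean within 2 cv d*."""
        space = build_model1(task_config)
        agent = td.AgentState(space)
        d_star = 30
        for _ in range(500):
            td.update_dwell_distribution(agent, "left_well", d_star, 1.0)
        D = agent.D[space.index("left_well")]
        mean_s = float(np.sum(np.arange(1, len(D) + 1) * D)) * space.kernel.dt
        assert abs(mean_s - 3.0) <= 2 * space.kernel.cv_d * 3.0

    def test_model2_dwell_is_fixed(self, task_config):
        agent = td.AgentState(build_model2(task_config))
        with pytest.raises(InvalidModelError):
            td.update_dwell_distribution(agent, 0, 10, 1.0)


class TestBlockTransitionLearning:
    def test_uniform_fixed_point(self, task_config):
        agent = td.AgentState(build_model2(task_config))
        td.update_block_transitions(agent, np.ones(4))
        np.testing.assert_allclose(agent.upper_row, 0.25, atol=1e-12)

    def test_full_bayes_replacement(self, task_config):
        agent = td.AgentState(build_model2(task_config),
                              params=td.LearningParams(eta_t=1.0))
        td.update_block_transitions(agent, np.array([1.0, 0, 0, 0]))
        np.testing.assert_allclose(agent.upper_row, [1, 0, 0, 0], atol=1e-12)

    def test_lesioned_floor_after_bayes_step(self, task_config):
        space = apply_model2_lesion(build_model2(task_config))
        agent = td.AgentState(space, params=td.LearningParams(eta_t=1.0))
        td.update_block_transitions(agent, np.array([1.0, 0, 0, 0]))
        expected = np.array([1.0, 0.15, 0.15, 0.15]) / 1.45
        np.testing.assert_allclose(agent.upper_row, expected, atol=1e-12)

    def test_converges_to_bayes_posterior(self, task_config):
        """Repeated identical evidence with eta_t < 1 converges to the
        normalized likelihood-prior product's fixed point."""
        agent = td.AgentState(build_model2(task_config),
                              params=td.LearningParams(eta_t=0.3))
        L = np.array([0.5, 0.3, 0.15, 0.05])
        for _ in range(400):
            td.update_block_transitions(agent, L)
        row = agent.upper_row
        post = L * row / np.dot(L, row)
        np.testing.assert_allclose(row, post, atol=1e-6)
        assert row.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_evidence_rejected(self, task_config):
        agent = td.AgentState(build_model2(task_config))
        with pytest.raises(DegenerateInputError):
            td.update_block_transitions(agent, np.zeros(4))

    def test_model1_rejected(self, task_config):
        agent = td.AgentState(build_model1(task_config))
        with pytest.raises(InvalidModelError):
            td.update_block_transitions(agent, np.ones(4))


def test_value_boundedness_under_bounded_rewards(task_config):
    """With rewards of at most 2 boluses and discounting, values stay within
    a small multiple of the maximum bolus count throughout learning."""
    from posmtd.experiment import _EngineState
    from posmtd.task_simulator import generate_stationary_session
    space = build_model1(task_config)
    agent = td.AgentState(space)
    eng = _EngineState(agent)
    for seed in range(3):
        sess = generate_stationary_session(task_config, n_trials=80,
                                           n_boluses=2, seed=seed)
        eng.run_session(sess)
        assert np.all(agent.V <= 4.0 + 1e-9) and np.all(agent.V >= -1.0)
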