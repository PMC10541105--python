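"""The forward recursions against the enumeration oracle and known limits."""

import numpy as np
import pytest

from conftest import make_toy_space, sample_sequence
from posmtd import belief_inference as bi
from posmtd.errors import ImpossibleObservationError, SizeError
from posmtd.state_spaces import dwell_survival


def _compare_trace_to_oracle(space, obs, atol):
    trace = bi.filter_sequence(space, obs)
    oracle = bi.brute_force_posterior(space, obs)
    np.testing.assert_allclose(np.array(trace.alpha), oracle.alpha, atol=atol)
    np.testing.assert_allclose(np.array(trace.state_belief),
                               oracle.state_belief, atol=atol)
    np.testing.assert_allclose(np.array(trace.beta), oracle.beta, atol=atol)
    np.testing.assert_allclose(np.array(trace.step_marginals),
                               oracle.step_marginals, atol=atol)
    ed_r = np.array(trace.expected_dwell)
    both = np.isfinite(ed_r) & np.isfinite(oracle.expected_dwell)
    defined = oracle.alpha > 1e-12
    assert not np.any(np.logical_xor(np.isfinite(ed_r),
                                     np.isfinite(oracle.expected_dwell)) & defined)
    np.testing.assert_allclose(ed_r[both & defined],
                               oracle.expected_dwell[both & defined], atol=atol)


class TestOracleEquivalence:
    def test_randomized_instances(self):
        """Recursive alpha/beta/belief/E[d] equal exhaustive enumeration on
        100 randomized toys (the hard correctness gate of the filter)."""
        rng = np.random.default_rng(2024)
        for i in range(100):
            n_states = int(rng.integers(2, 5))
            n_symbols = int(rng.integers(2, 5))
            n_dwell = int(rng.integers(2, 5))
            space = make_toy_space(i, n_states, n_symbols, n_dwell)
            obs = sample_sequence(space, rng, 8)
            _compare_trace_to_oracle(space, obs, atol=1e-8)

    def test_belief_normalized_every_step(self):
        rng = np.random.default_rng(7)
        for i in range(20):
            space = make_toy_space(100 + i)
            obs = sample_sequence(space, rng, 8)
            trace = bi.filter_sequence(space, obs)
            for b in trace.state_belief:
                assert b.sum() == pytest.approx(1.0, abs=1e-9)
            for bt in trace.beta:
                assert np.all(bt >= -1e-12) and bt.sum() <= 1 + 1e-9

    def test_beta_sums_to_one_at_non_empty_observation(self):
        """Non-empty observations reliably signal a transition, so the
        transition posterior is a full distribution there."""
        rng = np.random.default_rng(8)
        null = None
        for i in range(20):
            space = make_toy_space(200 + i)
            null = space.alphabet.null_index
            obs = sample_sequence(space, rng, 8)
            trace = bi.filter_sequence(space, obs)
            for t in range(1, len(obs)):
                if obs[t] != null:
                    assert trace.beta[t - 1].sum() == pytest.approx(1.0, abs=1e-9)


class TestLimits:
    def test_markov_limit_matches_hmm_forward(self):
        """Point-mass dwells at one step reduce the filter to ordinary HMM
        filtering; compare with a direct HMM forward pass."""
        rng = np.random.default_rng(3)
        for i in range(20):
            space = make_toy_space(300 + i, point_dwell=True)
            obs = sample_sequence(space, rng, 8)
            trace = bi.filter_sequence(space, obs)
            # independent HMM forward: every step emits from the entered state
            pi = np.zeros(space.n_states)
            pi[space.initial_index] = 1.0
            f = pi * space.O[:, obs[0]]
            f /= f.sum()
            np.testing.assert_allclose(trace.state_belief[0], f, atol=1e-10)
            for t in range(1, len(obs)):
                f = (space.T.T @ f) * space.O[:, obs[t]]
                f /= f.sum()
                np.testing.assert_allclose(trace.state_belief[t], f, atol=1e-10)

    def test_fully_observable_limit_is_indicator(self):
        space = make_toy_space(0, n_symbols=4, deterministic=True,
                               point_dwell=True)
        obs = ["o0", "o1", "o2", "o0"]
        trace = bi.filter_sequence(space, obs)
        for t, b in enumerate(trace.state_belief):
            assert set(np.round(b, 12)) <= {0.0, 1.0}
            assert b[(space.initial_index + t) % space.n_states] == pytest.approx(1.0)

    def test_deterministic_chain_alpha(self):
        space = make_toy_space(0, deterministic=True, point_dwell=True)
        trace = bi.filter_sequence(space, ["o0"])
        alpha = bi.alpha_update(space, trace)
        assert alpha[space.initial_index] == pytest.approx(1.0)
        # the forced next symbol has marginal 1
        assert bi.observation_marginal(space, trace, "o1") == pytest.approx(1.0)
        beta = bi.transition_posterior(space, trace, "o1")
        assert beta[space.initial_index] == pytest.approx(1.0)


class TestEdgeCases:
    def test_impossible_observation_names_symbol(self):
        space = make_toy_space(0, deterministic=True, point_dwell=True)
        trace = bi.filter_sequence(space, ["o0"])
        with pytest.raises(ImpossibleObservationError, match="o0"):
            bi.observation_marginal(space, trace, "o0")  # chain forces o1

    def test_null_after_observation_with_min_dwell_two(self):
        """With all dwell mass at d >= 2, no transition can follow one step
        after an entry, so the transition posterior is zero everywhere."""
        space = make_toy_space(4)
        D = np.zeros_like(space.D)
        D[:, 1:] = space.D[:, 1:] + space.D[:, [0]] / (space.D.shape[1] - 1)
        D /= D.sum(axis=1, keepdims=True)
        space = __import__("dataclasses").replace(space, D=D)
        sym = space.alphabet.symbols[0]
        trace = bi.filter_sequence(space, [sym])
        beta = bi.transition_posterior(space, trace, "null")
        np.testing.assert_allclose(beta, 0.0, atol=1e-12)

    def test_expected_dwell_point_mass(self):
        """Entry observed two steps ago and dwell fixed at 2 -> E[d] = 2."""
        space = make_toy_space(5)
        D = np.zeros_like(space.D)
        D[:, 1] = 1.0
        space = __import__("dataclasses").replace(space, D=D)
        sym = space.alphabet.symbols[0]
        trace = bi.filter_sequence(space, [sym, "null"])
        ed = bi.expected_dwell(space, trace)
        pos = np.array(trace.alpha[-1]) > 0
        assert pos.any()
        np.testing.assert_allclose(ed[pos], 2.0, atol=1e-12)

    def test_unreachable_state_has_zero_alpha(self):
        space = make_toy_space(6)
        T = space.T.copy()
        T[:, 2] = 0.0
        T /= T.sum(axis=1, keepdims=True)
        space = __import__("dataclasses").replace(space, T=T)
        obs = [space.alphabet.symbols[0], "null", "null"]
        trace = bi.filter_sequence(space, obs)
        # s2 unreachable and not initial: zero exit posterior after t=1 window
        for t in range(1, 3):
            if trace.t0[t] <= t:  # entries after the initial one
                pass
        assert trace.alpha[-1][2] == pytest.approx(0.0, abs=1e-15)

    def test_brute_force_size_guard(self):
        space = make_toy_space(0)
        with pytest.raises(SizeError):
            bi.brute_force_posterior(space, ["null"] * 11)

    def test_t0_bookkeeping(self):
        space = make_toy_space(0)
        sym = space.alphabet.symbols[0]
        trace = bi.filter_sequence(space, [sym, "null", "null", sym])
        assert trace.t0 == [0, 1, 2, 0]


def test_survival_replaces_density_in_belief_recursion():
    """The occupancy belief uses the inclusive dwell survival function: at an
    entry step both quantities coincide (S(1) = 1 sums the full density)."""
    space = make_toy_space(9)
    k = dwell_survival(space.D)
    np.testing.assert_allclose(k[:, 0], 1.0, atol=1e-12)
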