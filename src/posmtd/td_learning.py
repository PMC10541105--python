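"""Temporal-difference learning on belief states with dwell discounting.

The prediction error is *vectorized*: every state receives its own error,
gated by the transition posterior ``beta`` (the probability of having just
exited that state), with reward and successor value discounted by
``exp(-tau * E[d])`` for the expected dwell just spent.  Three learning
rules operate on the agent:

* state values, updated with the total error spread backward by an
  eligibility trace that records state visits since trial start;
* per-state dwell distributions (Model 1 only), nudged toward a Gaussian
  kernel centred on the observed inter-event duration;
* the upper-level block-transition row (Model 2 only), nudged toward the
  Bayesian posterior over blocks given the trial's observation likelihoods.

The total error also maps onto an equivalent dopamine firing rate around a
3 Hz baseline, with asymmetric scaling (gain 5 above baseline, 2 below)
reflecting the compressed representation of negative errors in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import belief_inference as bi
from .errors import ConfigurationError, DegenerateInputError, InvalidModelError
from .state_spaces import StateSpace, dwell_survival, gaussian_dwell_kernel


@dataclass(frozen=True)
class LearningParams:
    """Learning-rule parameters (all rates unitless, per update).

    ``tau`` is the temporal discount per grid step applied through
    ``exp(-tau * E[d])``; ``eta_r`` the value learning rate; ``gamma`` the
    eligibility decay; ``eta_d`` the dwell-distribution learning rate;
    ``eta_t`` the upper-level transition learning rate (no canonical value —
    matched to eta_d's order).  ``discount_growth`` switches the discount to
    the growth form ``exp(+tau * E[d])`` for sensitivity checks.
    """

    tau: float = 0.05
    eta_r: float = 0.5
    gamma: float = 0.95
    eta_d: float = 0.3
    eta_t: float = 0.3
    discount_growth: bool = False

    def __post_init__(self):
        for name in ("eta_r", "gamma", "eta_d", "eta_t"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        if self.tau <= 0:
            raise ConfigurationError("tau must be > 0")

    def discount(self, expected_dwell_steps):
        sign = 1.0 if self.discount_growth else -1.0
        return np.exp(sign * self.tau * np.asarray(expected_dwell_steps, dtype=float))


@dataclass(frozen=True)
class FiringParams:
    """Map from total prediction error to firing rate (Hz).

    ``baseline + k1 * delta`` for positive errors; negative errors suppress
    firing below baseline with slope ``k2_magnitude`` (rates floored at
    0 Hz).  ``printed_k2_form=True`` instead adds ``k2 * delta`` with
    k2 = -k2_magnitude literally, which *raises* firing on negative errors.
    """

    baseline: float = 3.0
    k1: float = 5.0
    k2_magnitude: float = 2.0
    printed_k2_form: bool = False

    def __post_init__(self):
        if self.baseline <= 0 or self.k1 <= 0 or self.k2_magnitude <= 0:
            raise ConfigurationError("firing parameters must be positive")


def firing_rate_from_pe(fp: FiringParams, total_delta) -> float | np.ndarray:
    """Convert total prediction error(s) to equivalent firing rate in Hz."""
    d = np.asarray(total_delta, dtype=float)
    if fp.printed_k2_form:
        neg = fp.baseline - fp.k2_magnitude * d      # k2 = -magnitude, literally
    else:
        neg = fp.baseline - fp.k2_magnitude * np.abs(d)
    rate = np.where(d >= 0.0, fp.baseline + fp.k1 * d, neg)
    rate = np.maximum(rate, 0.0)
    return float(rate) if rate.ndim == 0 else rate


@dataclass
class PredictionErrorRecord:
    """Vectorized prediction error at one step."""

    t: int
    per_state_delta: np.ndarray
    total_delta: float
    event_tag: str | None = None
    trial: int | None = None
    block: int | None = None


@dataclass
class AgentState:
    """Mutable learner state: values, eligibility, and the learned model.

    ``T`` and ``D`` start as copies of the task space's matrices; Model 1
    learns ``D`` online, Model 2 learns only the inter-trial ->
    trial-start row of ``T``.  ``space_view()`` exposes the learned model as
    a StateSpace sharing this agent's arrays, for use with the belief
    filter.
    """

    space: StateSpace
    params: LearningParams = field(default_factory=LearningParams)
    V: np.ndarray = None
    E: np.ndarray = None
    T: np.ndarray = None
    D: np.ndarray = None

    def __post_init__(self):
        S = self.space.n_states
        if self.V is None:
            self.V = np.zeros(S)
        if self.E is None:
            self.E = np.zeros(S)
        if self.T is None:
            self.T = self.space.T.copy()
        if self.D is None:
            self.D = self.space.D.copy()
        self._view = replace(self.space, T=self.T, D=self.D)

    @property
    def dwell_plastic(self) -> bool:
        return self.space.dwell_plastic

    def space_view(self) -> StateSpace:
        return self._view

    @property
    def upper_row(self) -> np.ndarray:
        """Learned inter-trial -> trial-start probabilities (Model 2)."""
        if self.space.model != 2:
            raise InvalidModelError("upper_row is a Model 2 quantity")
        i = self.space.initial_index
        cols = [self.space.index(ts) for ts in self.space.trial_start_states]
        return self.T[i, cols]


def successor_value_expectation(space: StateSpace, agent: AgentState,
                                state, o_next) -> float:
    """E[V of the successor | exited ``state``, next observation] (Eq.-14 form):
    a T*O-weighted average of the successor values."""
    s = space.index(state) if isinstance(state, str) else int(state)
    o = bi._as_symbol_index(space, o_next)
    w = agent.T[s] * space.O[:, o]
    denom = w.sum()
    if denom <= 0.0:
        raise ImpossibleSuccessorError(space, s, o)
    return float(w @ agent.V / denom)


class ImpossibleSuccessorError(DegenerateInputError):
    def __init__(self, space, s, o):
        super().__init__(
            f"no successor of state {space.state_labels[s]!r} can emit "
            f"{space.alphabet.symbols[o]!r}")


def prediction_error(space: StateSpace, agent: AgentState, trace,
                     reward: float, o_next, *, event_tag=None, trial=None,
                     block=None) -> PredictionErrorRecord:
    """Vectorized dwell-discounted TD error for the upcoming observation.

    ``delta_s = beta_s * (g(E[d_s]) * (r + E[V_succ|s]) - V_s)`` with
    ``g(d) = exp(-tau d)``; states with zero transition posterior contribute
    nothing (which also covers the undefined-dwell sentinel, since the
    expected dwell is undefined only where the exit posterior is zero).
    """
    view = agent.space_view()
    beta = bi.transition_posterior(view, trace, o_next)
    ed = bi.expected_dwell(view, trace)
    o = bi._as_symbol_index(space, o_next)
    S = space.n_states
    delta = np.zeros(S)
    for s in range(S):
        if beta[s] <= 0.0:
            continue
        g = float(agent.params.discount(ed[s]))
        ev = successor_value_expectation(space, agent, s, o)
        delta[s] = beta[s] * (g * (reward + ev) - agent.V[s])
    return PredictionErrorRecord(t=trace.t, per_state_delta=delta,
                                 total_delta=float(delta.sum()),
                                 event_tag=event_tag, trial=trial, block=block)


def update_eligibility(agent: AgentState, beta) -> AgentState:
    """E_s <- max(gamma * E_s, beta_s); call once per step before the value
    update.  Use :func:`reset_eligibility` at each trial start."""
    np.maximum(agent.params.gamma * agent.E, np.asarray(beta, dtype=float),
               out=agent.E)
    return agent


def reset_eligibility(agent: AgentState) -> AgentState:
    agent.E[:] = 0.0
    return agent


def update_values(agent: AgentState, total_delta: float) -> AgentState:
    """V_s <- V_s + eta_r * E_s * total_delta."""
    agent.V += agent.params.eta_r * agent.E * float(total_delta)
    return agent


def update_dwell_distribution(agent: AgentState, state, observed_duration,
                              beta_s: float) -> AgentState:
    """Nudge one state's dwell distribution toward the observed duration.

    ``D_s <- D_s + eta_d * beta_s * (K_d - D_s)`` where ``K_d`` is the
    floored Gaussian kernel centred on ``observed_duration`` (steps).
    Model 2 dwell distributions are fixed by construction.
    """
    if not agent.dwell_plastic:
        raise InvalidModelError("dwell distributions are fixed in this model")
    s = agent.space.index(state) if isinstance(state, str) else int(state)
    K = gaussian_dwell_kernel(observed_duration, agent.space.kernel)
    agent.D[s] += agent.params.eta_d * float(beta_s) * (K - agent.D[s])
    return agent


def update_dwell_distributions(agent: AgentState, observed_duration,
                               beta) -> AgentState:
    """Vectorized dwell update for all states at a non-empty observation."""
    if not agent.dwell_plastic:
        raise InvalidModelError("dwell distributions are fixed in this model")
    K = gaussian_dwell_kernel(observed_duration, agent.space.kernel)
    b = np.asarray(beta, dtype=float)[:, None]
    agent.D += agent.params.eta_d * b * (K[None, :] - agent.D)
    return agent


def update_block_transitions(agent: AgentState, trial_likelihoods=None, *,
                             log_likelihoods=None) -> AgentState:
    """Move the upper-level row toward the posterior over blocks.

    ``T_n <- T_n + eta_t * (L_n T_n / sum_i L_i T_i - T_n)`` where ``L_n``
    is the probability of the trial's observation sequence under block n's
    subgraph.  Under the lesion the 0.15 floor is reapplied afterwards.
    """
    if agent.space.model != 2:
        raise InvalidModelError("block-transition learning is a Model 2 rule")
    if log_likelihoods is not None:
        ll = np.asarray(log_likelihoods, dtype=float)
        L = np.exp(ll - ll.max())
    else:
        L = np.asarray(trial_likelihoods, dtype=float)
    if np.all(L <= 0.0) or not np.all(np.isfinite(L)):
        raise DegenerateInputError("trial likelihoods are all zero or invalid")
    i = agent.space.initial_index
    cols = [agent.space.index(ts) for ts in agent.space.trial_start_states]
    row = agent.T[i, cols]
    post = L * row
    z = post.sum()
    if z <= 0.0:
        raise DegenerateInputError("posterior over blocks is degenerate")
    post /= z
    row = row + agent.params.eta_t * (post - row)
    floor = agent.space.upper_row_floor
    if floor is not None:
        row = np.maximum(row, floor)
        row = row / row.sum()
    agent.T[i, cols] = row
    return agent
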