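"""Belief-state filtering in a partially observable semi-Markov process.

The agent never observes its state directly.  States emit a single
observation on *entry* (often the empty symbol, with probability
``O[s, null]``); between entries the observation is empty with certainty, so
every non-empty observation reliably signals a transition into a new state,
while transitions may also pass silently.  Filtering therefore reduces to
reasoning about *when the last few entries happened*:

* ``alpha[s, t]``  = P(s_t = s and the process exits s at t | o_1..o_t),
  computed by summing over the dwell time d spent in s — the entry happened
  at t-d+1, emitting the observation seen there — weighted by the dwell
  probability ``D[s, d]`` and the (recursively computed) probability that
  some predecessor exited at t-d.
* ``beta[s, t]``   = P(exited s at t | o_1..o_{t+1}), the transition
  posterior: ``alpha`` reweighted by how well s's successors explain the
  next observation.  It gates the vectorized prediction errors.
* the state belief replaces the dwell density with its survival function
  (still inside s rather than exiting), and the expected dwell
  ``E[d_{s,t}]`` is the conditional mean of d given an exit now.

All recursions are exact for this generative model; the module also contains
:func:`brute_force_posterior`, an independent oracle that enumerates every
(state sequence, dwell sequence) hypothesis on small instances and computes
the same posteriors by direct summation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ImpossibleObservationError, SizeError
from .state_spaces import StateSpace, dwell_survival

__all__ = [
    "BeliefTrace", "new_trace", "append_observation", "filter_sequence",
    "alpha_update", "state_belief_update", "expected_dwell",
    "observation_marginal", "transition_posterior",
    "brute_force_posterior", "PosteriorSummary",
]


@dataclass
class BeliefTrace:
    """Filtering history over one observation sequence.

    Lists are indexed by 0-based step ``i`` (time t = i+1): ``alpha[i]``,
    ``state_belief[i]`` and ``expected_dwell[i]`` (steps; NaN where the exit
    posterior is zero) refer to time i+1 given o_1..o_{i+1};
    ``step_marginals[i]`` is P(o_{i+1} | o_1..o_i); ``beta[i]`` is the
    transition posterior at time i+1 given o_1..o_{i+2} (one entry shorter).
    ``t0[i]`` counts steps since the last non-empty observation (0 at one).
    """

    initial_belief: np.ndarray
    observations: list = field(default_factory=list)
    alpha: list = field(default_factory=list)
    beta: list = field(default_factory=list)
    state_belief: list = field(default_factory=list)
    expected_dwell: list = field(default_factory=list)
    step_marginals: list = field(default_factory=list)
    t0: list = field(default_factory=list)
    _last_obs_time: int = 0          # 1-based time of last non-empty obs, 0 if none
    _truncation_warned: bool = False

    @property
    def t(self) -> int:
        return len(self.observations)

    def to_frame(self, space: StateSpace):
        """Long-format table (one row per step x state) for inspection."""
        import pandas as pd

        rows = []
        for i in range(self.t):
            for s, label in enumerate(space.state_labels):
                rows.append({
                    "t": i + 1, "state": label,
                    "alpha": self.alpha[i][s],
                    "beta": self.beta[i][s] if i < len(self.beta) else np.nan,
                    "belief": self.state_belief[i][s],
                    "expected_dwell": self.expected_dwell[i][s],
                })
        return pd.DataFrame(rows)


def new_trace(space: StateSpace, initial_belief=None) -> BeliefTrace:
    if initial_belief is None:
        pi = np.zeros(space.n_states)
        pi[space.initial_index] = 1.0
    else:
        pi = np.asarray(initial_belief, dtype=float)
        if pi.shape != (space.n_states,) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("initial_belief must be a distribution over states")
    return BeliefTrace(initial_belief=pi)


def _as_symbol_index(space: StateSpace, symbol) -> int:
    if isinstance(symbol, str):
        return space.alphabet.index(symbol)
    return int(symbol)


def _forward_terms(space: StateSpace, trace: BeliefTrace):
    """Unnormalized forward terms at t = len(observations), relative to L_{t-1}.

    Returns ``(u, b, ed_num)`` where ``u[s] / sum(b)`` is alpha,
    ``b[s] / sum(b)`` the state belief, and ``ed_num[s] / u[s]`` the expected
    dwell in steps.  Entry hypotheses k run from the most recent non-empty
    observation (an entry observed later than k would contradict a dwell
    covering it) back no further than the dwell grid allows.
    """
    t = trace.t
    if t == 0:
        raise ValueError("trace has no observations")
    obs = trace.observations
    n_d = space.kernel.n_steps
    null = space.alphabet.null_index
    S = space.n_states
    D = space.D
    SURV = dwell_survival(space.D)

    last_obs = t if obs[t - 1] != null else trace._last_obs_time
    k_low = max(1, t - n_d + 1, last_obs if last_obs > 0 else 1)
    if last_obs > 0 and last_obs < t - n_d + 1 and not trace._truncation_warned:
        warnings.warn(
            "time since last non-empty observation exceeds the dwell grid; "
            "mass beyond d_max is treated as zero", RuntimeWarning)
        trace._truncation_warned = True

    u = np.zeros(S)
    b = np.zeros(S)
    ed_num = np.zeros(S)
    for k in range(k_low, t + 1):
        if k == 1:
            W = trace.initial_belief
        else:
            W = space.T.T @ trace.alpha[k - 2]
        # 1 / prod(c_j, j = k..t-1): converts P(. , o_1..o_{k-1}) scale to L_{t-1}
        inv_h = 1.0
        for j in range(k, t):
            inv_h /= trace.step_marginals[j - 1]
        d = t - k + 1
        ow = space.O[:, obs[k - 1]] * W * inv_h
        u += ow * D[:, d - 1]
        b += ow * SURV[:, d - 1]
        ed_num += ow * D[:, d - 1] * d
    return u, b, ed_num


def alpha_update(space: StateSpace, trace: BeliefTrace) -> np.ndarray:
    """Exit posterior alpha_{s,t} at the trace's current end time."""
    u, b, _ = _forward_terms(space, trace)
    c = b.sum()
    if c <= 0.0:
        sym = space.alphabet.symbols[trace.observations[-1]]
        raise ImpossibleObservationError(
            f"observation {sym!r} at t={trace.t} has zero probability")
    return u / c


def state_belief_update(space: StateSpace, trace: BeliefTrace) -> np.ndarray:
    """Occupancy belief P(s_t = s | o_1..o_t): alpha's recursion with the
    dwell density replaced by its survival function."""
    _, b, _ = _forward_terms(space, trace)
    c = b.sum()
    if c <= 0.0:
        sym = space.alphabet.symbols[trace.observations[-1]]
        raise ImpossibleObservationError(
            f"observation {sym!r} at t={trace.t} has zero probability")
    return b / c


def expected_dwell(space: StateSpace, trace: BeliefTrace) -> np.ndarray:
    """E[d_{s,t}] in steps, conditional on exiting s now; NaN where that
    event has zero posterior probability (undefined-dwell sentinel)."""
    u, _, ed_num = _forward_terms(space, trace)
    out = np.full(space.n_states, np.nan)
    pos = u > 0.0
    out[pos] = ed_num[pos] / u[pos]
    return out


def observation_marginal(space: StateSpace, trace: BeliefTrace, o_next) -> float:
    """One-step predictive probability P(o_{t+1} | o_1..o_t).

    Conditions on whether a transition occurs at t: if it does, the entered
    state emits ``o_next``; if not, the observation is empty with certainty.
    """
    o = _as_symbol_index(space, o_next)
    null = space.alphabet.null_index
    if trace.t == 0:
        m = float(trace.initial_belief @ space.O[:, o])
    else:
        alpha = alpha_update(space, trace)
        belief = state_belief_update(space, trace)
        pvec = space.T @ space.O[:, o]
        m = float(pvec @ alpha)
        if o == null:
            m += float(max(0.0, belief.sum() - alpha.sum()))
    if m <= 0.0:
        raise ImpossibleObservationError(
            f"observation {space.alphabet.symbols[o]!r} is impossible at "
            f"t={trace.t + 1}")
    return m


def transition_posterior(space: StateSpace, trace: BeliefTrace, o_next) -> np.ndarray:
    """beta_{s,t}: probability of having just exited s, given o_1..o_{t+1}."""
    o = _as_symbol_index(space, o_next)
    alpha = alpha_update(space, trace)
    pvec = space.T @ space.O[:, o]
    m = observation_marginal(space, trace, o)
    return pvec * alpha / m


def append_observation(space: StateSpace, trace: BeliefTrace, symbol) -> BeliefTrace:
    """Advance the trace by one observation, storing all step quantities."""
    o = _as_symbol_index(space, symbol)
    null = space.alphabet.null_index
    if trace.t > 0:
        trace.beta.append(transition_posterior(space, trace, o))
    trace.observations.append(o)
    u, b, ed_num = _forward_terms(space, trace)
    c = float(b.sum())
    if c <= 0.0:
        raise ImpossibleObservationError(
            f"observation {space.alphabet.symbols[o]!r} at t={trace.t} has "
            "zero probability")
    trace.alpha.append(u / c)
    trace.state_belief.append(b / c)
    ed = np.full(space.n_states, np.nan)
    pos = u > 0.0
    ed[pos] = ed_num[pos] / u[pos]
    trace.expected_dwell.append(ed)
    trace.step_marginals.append(c)
    if o != null:
        trace.t0.append(0)
        trace._last_obs_time = trace.t
    else:
        trace.t0.append((trace.t0[-1] + 1) if trace.t0 else 1)
    return trace


def filter_sequence(space: StateSpace, observations, initial_belief=None) -> BeliefTrace:
    """Run the forward filter over a whole observation sequence."""
    trace = new_trace(space, initial_belief)
    for sym in observations:
        append_observation(space, trace, sym)
    return trace


# ---------------------------------------------------------------------------
# brute-force enumeration oracle
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Posterior quantities per step (row i is time t = i+1).

    ``beta`` has one fewer row; ``beta[i]`` is the transition posterior at
    time i+1 given observations through i+2.
    """

    alpha: np.ndarray
    beta: np.ndarray
    state_belief: np.ndarray
    expected_dwell: np.ndarray
    step_marginals: np.ndarray


_MAX_PATHS = 2_000_000


def brute_force_posterior(space: StateSpace, observations,
                          initial_belief=None) -> PosteriorSummary:
    """Exact posteriors by exhaustive enumeration of (states, dwells).

    Enumerates every segmentation of the observed window into state visits
    with explicit dwell times, scores each against the generative model
    (entry emission x dwell probability x transition probabilities; empty
    observations between entries), and sums.  Intended as an independent
    oracle for the recursive filter on small instances.
    """
    T_total = len(observations)
    S = space.n_states
    n_d = space.kernel.n_steps
    if S > 5 or T_total > 10:
        raise SizeError("brute force limited to <= 5 states and <= 10 steps")
    obs = [_as_symbol_index(space, s) for s in observations]
    null = space.alphabet.null_index
    if initial_belief is None:
        pi = np.zeros(S)
        pi[space.initial_index] = 1.0
    else:
        pi = np.asarray(initial_belief, dtype=float)
    Tm, Om, Dm = space.T, space.O, space.D
    SURV = dwell_survival(Dm)

    alpha = np.zeros((T_total, S))
    beta = np.zeros((max(T_total - 1, 0), S))
    belief = np.zeros((T_total, S))
    ed = np.full((T_total, S), np.nan)
    marginals = np.zeros(T_total)

    paths = 0
    prev_L = 1.0
    for t_end in range(1, T_total + 1):
        L = 0.0
        a_num = np.zeros(S)
        b_num = np.zeros(S)
        ed_num = np.zeros(S)
        exited_prev = np.zeros(S)

        def rec(k, prev, w):
            nonlocal L, paths
            # longest time e >= k such that o_{k+1}..o_e are all empty
            e_max = k
            while e_max < t_end and obs[e_max] == null:
                e_max += 1
            for s in range(S):
                w_in = pi[s] if prev < 0 else Tm[prev, s]
                if w_in <= 0.0:
                    continue
                we = w * w_in * Om[s, obs[k - 1]]
                if we <= 0.0:
                    continue
                # terminal segment covering through t_end
                occ = t_end - k + 1
                if occ <= n_d and e_max >= t_end:
                    paths += 1
                    if paths > _MAX_PATHS:
                        raise SizeError("enumeration exceeds path budget")
                    w_exit = we * Dm[s, occ - 1]
                    w_surv = we * (SURV[s, occ] if occ < n_d else 0.0)
                    L += w_exit + w_surv
                    b_num[s] += w_exit + w_surv
                    a_num[s] += w_exit
                    ed_num[s] += occ * w_exit
                    if k == t_end and prev >= 0:
                        exited_prev[prev] += w_exit + w_surv
                # completed segments followed by another entry
                for d in range(1, min(n_d, t_end - k) + 1):
                    if k + d - 1 > e_max:
                        break
                    wd = we * Dm[s, d - 1]
                    if wd > 0.0:
                        rec(k + d, s, wd)

        rec(1, -1, 1.0)
        i = t_end - 1
        marginals[i] = L / prev_L
        if L <= 0.0:
            raise ImpossibleObservationError(
                f"sequence impossible under the model at t={t_end}")
        alpha[i] = a_num / L
        belief[i] = b_num / L
        pos = a_num > 0.0
        ed[i, pos] = ed_num[pos] / a_num[pos]
        if t_end >= 2:
            beta[i - 1] = exited_prev / L
        prev_L = L
    return PosteriorSummary(alpha=alpha, beta=beta, state_belief=belief,
                            expected_dwell=ed, step_marginals=marginals)
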