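"""Full simulations: control/lesion x Model 1/Model 2, with the averaging
protocol used for the headline comparisons.

A *run* is one independent agent experiencing ``n_sessions`` sessions in a
row, its values, dwell distributions and upper-level transition row
persisting throughout; the first ``burn_in_sessions`` sessions are excluded
from every summary so that initialization transients do not contaminate the
averages, and summaries are means across ``n_runs`` independent runs.

Two execution paths produce identical prediction-error streams: a
pure-Python reference orchestrator assembled from the module-level
operations (used in tests, where it is pinned against the enumeration
oracle) and a compiled engine (:mod:`posmtd._engine`) used by default for
the full-scale conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import belief_inference as bi
from . import td_learning as td
from ._engine import run_session_engine
from .config import TaskConfig
from .errors import SchemaError, WindowingError
from .state_spaces import (StateSpace, apply_model2_lesion, build_model1,
                           build_model1_lesioned, build_model2, dwell_survival)
from .task_simulator import (DELIVERY_TAGS, OMISSION_TAGS, Session,
                             SessionConfig, generate_session)

REWARD_EVENT_TAGS = ("2sh_reward", "2lo_omission", "3bg_bolus1",
                     "3bg_bolus2", "4bg_bolus2", "4sm_omission")


@dataclass(frozen=True)
class ExperimentConfig:
    model: int = 1
    lesion: bool = False
    n_runs: int = 20
    n_sessions: int = 30
    burn_in_sessions: int = 10
    early_n: int = 5
    late_n: int = 5
    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    learning: td.LearningParams = field(default_factory=td.LearningParams)
    firing: td.FiringParams = field(default_factory=td.FiringParams)
    include_free_choice: bool = False
    side_a_is_left: bool | None = None
    use_engine: bool = True
    verbose: bool = False

    @property
    def condition(self) -> str:
        return f"model{self.model}-{'lesion' if self.lesion else 'control'}"


def build_space(model: int, lesion: bool, task: TaskConfig) -> StateSpace:
    if model == 1:
        return build_model1_lesioned(task) if lesion else build_model1(task)
    space = build_model2(task)
    return apply_model2_lesion(space) if lesion else space


# ---------------------------------------------------------------------------
# block subgraphs for the Model 2 trial-likelihood (Eq.-24 evidence)
# ---------------------------------------------------------------------------

def block_subspaces(agent: td.AgentState) -> list[StateSpace]:
    """Per-block subgraphs (block states + inter-trial state) used to score a
    trial's observation sequence under each block hypothesis."""
    space = agent.space
    subs = []
    for b in sorted(space.block_states):
        labels = list(space.block_states[b]) + [space.initial_state]
        idx = [space.index(l) for l in labels]
        Tsub = agent.T[np.ix_(idx, idx)].copy()
        iti_sub = len(labels) - 1
        Tsub[iti_sub, :] = 0.0
        Tsub[iti_sub, 0] = 1.0          # trial-start state is first member
        subs.append(StateSpace(
            state_labels=tuple(labels), alphabet=space.alphabet,
            T=Tsub, O=space.O[idx].copy(), D=agent.D[idx].copy(),
            kernel=space.kernel, level=tuple("lower" for _ in labels),
            model=1, dwell_plastic=False,
            initial_state=labels[0], meta={"block": b},
        ))
    return subs


def trial_log_likelihoods(subspaces, obs_window) -> np.ndarray:
    """Log P(observation window | block) for each block subgraph, as the sum
    of log one-step observation marginals with a point-mass entry into the
    block's trial-start state at the window start."""
    out = np.empty(len(subspaces))
    for j, sub in enumerate(subspaces):
        pi = np.zeros(sub.n_states)
        pi[sub.initial_index] = 1.0
        trace = bi.filter_sequence(sub, obs_window, initial_belief=pi)
        out[j] = float(np.sum(np.log(trace.step_marginals)))
    return out


# ---------------------------------------------------------------------------
# session execution: reference orchestrator and compiled engine
# ---------------------------------------------------------------------------

def run_session_reference(agent: td.AgentState, session: Session) -> np.ndarray:
    """One session of filtering + learning using the per-module operations.

    Returns ``out[t]`` = total prediction error computed in response to the
    observation at step t.  Mutates the agent (values, eligibility, dwell
    distributions, upper-level row) exactly as the compiled engine does.
    """
    space = agent.space_view()
    obs, rewards = session.concatenate()
    null = space.alphabet.null_index
    light = space.alphabet.index("light_on")
    model2 = space.model == 2
    subs = block_subspaces(agent) if model2 else None
    trace = bi.new_trace(space)
    out = np.zeros(len(obs))
    prev_light = -1
    last_obs = -1
    for t in range(len(obs)):
        bi.append_observation(space, trace, obs[t])
        if obs[t] != null:
            last_obs = t
        if t + 1 >= len(obs):
            break
        o_next = int(obs[t + 1])
        r_next = float(rewards[t + 1])
        if o_next == light:
            if model2 and prev_light >= 0:
                ll = trial_log_likelihoods(subs, obs[prev_light:t + 1])
                td.update_block_transitions(agent, log_likelihoods=ll)
            prev_light = t + 1
            td.reset_eligibility(agent)
        rec = td.prediction_error(space, agent, trace, r_next, o_next)
        beta = bi.transition_posterior(space, trace, o_next)
        td.update_eligibility(agent, beta)
        td.update_values(agent, rec.total_delta)
        if space.dwell_plastic and o_next != null and last_obs >= 0:
            td.update_dwell_distributions(agent, t + 1 - last_obs, beta)
        out[t + 1] = rec.total_delta
    return out


class _EngineState:
    """Per-run arrays shared with the compiled engine across sessions."""

    def __init__(self, agent: td.AgentState):
        space = agent.space
        self.agent = agent
        self.surv = dwell_survival(agent.D)
        self.null = space.alphabet.null_index
        self.light = space.alphabet.index("light_on")
        self.init_state = space.initial_index
        if space.model == 2:
            subs = block_subspaces(agent)
            smax = max(s.n_states for s in subs)
            n_d = space.kernel.n_steps
            M = len(space.alphabet)
            self.subT = np.zeros((len(subs), smax, smax))
            self.subO = np.zeros((len(subs), smax, M))
            self.subD = np.zeros((len(subs), smax, n_d))
            self.subSURV = np.zeros((len(subs), smax, n_d))
            self.sub_init = np.zeros(len(subs), dtype=np.int64)
            for j, sub in enumerate(subs):
                n = sub.n_states
                self.subT[j, :n, :n] = sub.T
                self.subO[j, :n] = sub.O
                self.subD[j, :n] = sub.D
                self.subSURV[j, :n] = dwell_survival(sub.D)
                self.sub_init[j] = sub.initial_index
            self.iti_idx = space.initial_index
            self.ts_idx = np.array([space.index(l) for l in space.trial_start_states],
                                   dtype=np.int64)
            self.upper = True
        else:
            one = np.zeros((1, 1, 1))
            self.subT = self.subO = self.subD = self.subSURV = one
            self.sub_init = np.zeros(1, dtype=np.int64)
            self.iti_idx = 0
            self.ts_idx = np.zeros(1, dtype=np.int64)
            self.upper = False

    def run_session(self, session: Session) -> np.ndarray:
        agent = self.agent
        space = agent.space
        p = agent.params
        obs, rewards = session.concatenate()
        out = np.zeros(len(obs))
        run_session_engine(
            obs, rewards,
            agent.T, space.O, agent.D, self.surv, agent.V, agent.E,
            self.init_state, self.null, self.light,
            p.tau, p.eta_r, p.gamma, p.discount_growth,
            space.dwell_plastic, p.eta_d, space.kernel.cv_d,
            space.kernel.dt, space.kernel.d_b,
            self.upper, self.iti_idx, self.ts_idx, p.eta_t,
            space.upper_row_floor if space.upper_row_floor else -1.0,
            self.subT, self.subO, self.subD, self.subSURV, self.sub_init,
            out,
        )
        return out


def run_session_fast(agent: td.AgentState, session: Session) -> np.ndarray:
    """Compiled counterpart of :func:`run_session_reference`."""
    return _EngineState(agent).run_session(session)


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    config: ExperimentConfig
    records: pd.DataFrame

    @property
    def condition(self) -> str:
        return self.config.condition

    def post_burn_in(self) -> pd.DataFrame:
        return self.records[self.records["session"] >= self.config.burn_in_sessions]


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run ``n_runs`` independent agents through the task and collect the
    event-aligned prediction errors (and equivalent firing rates)."""
    space = build_space(config.model, config.lesion, config.task)
    ss = np.random.SeedSequence(config.seed)
    frames = []
    for run, child in enumerate(ss.spawn(config.n_runs)):
        rng = np.random.default_rng(child)
        session_seeds = rng.integers(2 ** 31, size=config.n_sessions)
        agent = td.AgentState(space, params=config.learning)
        engine = _EngineState(agent) if config.use_engine else None
        abs_deltas = []
        for s_idx in range(config.n_sessions):
            session = generate_session(SessionConfig(
                task=config.task,
                include_free_choice=config.include_free_choice,
                side_a_is_left=config.side_a_is_left,
                seed=int(session_seeds[s_idx])))
            if engine is not None:
                out = engine.run_session(session)
            else:
                out = run_session_reference(agent, session)
            tab = session.event_table()
            tab["total_delta"] = out[tab["step"].to_numpy()]
            tab["run"] = run
            tab["session"] = s_idx
            frames.append(tab)
            abs_deltas.append(float(np.mean(np.abs(out))))
        if config.verbose:
            print(f"[{config.condition}] run {run}: seed={child.entropy} "
                  f"sessions={config.n_sessions} "
                  f"mean|PE|={np.mean(abs_deltas):.4f}")
    records = pd.concat(frames, ignore_index=True)
    records["firing_hz"] = td.firing_rate_from_pe(
        config.firing, records["total_delta"].to_numpy())
    records["event_tag"] = records.pop("tag")
    records["trial"] = records["trial_in_block"]
    records["post_burn_in"] = records["session"] >= config.burn_in_sessions
    return ExperimentResult(config=config, records=records)


# ---------------------------------------------------------------------------
# event-aligned summaries
# ---------------------------------------------------------------------------

@dataclass
class EventAlignedSummary:
    """Across-run means of event-aligned responses.

    ``per_run`` holds one row per (run, tag-or-contrast, window);
    ``table`` aggregates mean and across-run s.d. over exactly n_runs runs.
    """

    condition: str
    per_run: pd.DataFrame
    table: pd.DataFrame
    early_n: int
    late_n: int
    n_runs: int


def _windowed(group: pd.DataFrame, early_n: int, late_n: int, value: str):
    g = group.sort_values("trial")
    v = g[value].to_numpy()
    if len(v) < early_n + late_n:
        raise WindowingError(
            f"only {len(v)} events for windows of {early_n}+{late_n}")
    return v[0], v[:early_n].mean(), v[-late_n:].mean()


def summarize_reward_responses(result: ExperimentResult, *, early_n=None,
                               late_n=None, burn_in=None,
                               tags=REWARD_EVENT_TAGS) -> EventAlignedSummary:
    """First-trial / first-k / last-k mean responses per reward event tag.

    Events are ordered by their trial within the block; per-run values
    average over the post-burn-in sessions, and the summary table averages
    over runs.
    """
    cfg = result.config
    early_n = early_n or cfg.early_n
    late_n = late_n or cfg.late_n
    burn_in = cfg.burn_in_sessions if burn_in is None else burn_in
    rec = result.records
    rec = rec[(rec["session"] >= burn_in) & rec["event_tag"].isin(tags)]
    rows = []
    for (run, session, tag), g in rec.groupby(["run", "session", "event_tag"],
                                              observed=True):
        for value, unit in (("total_delta", "delta"), ("firing_hz", "hz")):
            first, early, late = _windowed(g, early_n, late_n, value)
            rows.append({"run": run, "session": session, "tag": tag,
                         "unit": unit, "first_trial": first, "early": early,
                         "late": late})
    if len(rows) == 0:
        raise WindowingError("no events after burn-in")
    by_sess = pd.DataFrame(rows)
    per_run = (by_sess.groupby(["run", "tag", "unit"], observed=True)
               [["first_trial", "early", "late"]].mean().reset_index())
    table = (per_run.groupby(["tag", "unit"], observed=True)
             [["first_trial", "early", "late"]]
             .agg(["mean", "std"]))
    table.columns = ["_".join(c) for c in table.columns]
    return EventAlignedSummary(condition=result.condition, per_run=per_run,
                               table=table.reset_index(), early_n=early_n,
                               late_n=late_n, n_runs=cfg.n_runs)


def summarize_cue_responses(result: ExperimentResult, *, early_n=None,
                            late_n=None, burn_in=None) -> EventAlignedSummary:
    """High- vs low-value cue responses, early and late in each block.

    The high/low label comes from the programmed contingencies (the side with
    the shorter delay or larger reward), not from learned values, so the
    label is stable across learning.
    """
    cfg = result.config
    early_n = early_n or cfg.early_n
    late_n = late_n or cfg.late_n
    burn_in = cfg.burn_in_sessions if burn_in is None else burn_in
    rec = result.records
    rec = rec[(rec["session"] >= burn_in) & (rec["event_tag"] == "cue")]
    rows = []
    for (run, session, block, value), g in rec.groupby(
            ["run", "session", "block", "cue_value"], observed=True):
        for col, unit in (("total_delta", "delta"), ("firing_hz", "hz")):
            first, early, late = _windowed(g, early_n, late_n, col)
            rows.append({"run": run, "session": session, "block": block,
                         "cue_value": value, "unit": unit,
                         "first_trial": first, "early": early, "late": late})
    by_sess = pd.DataFrame(rows)
    per_run = (by_sess.groupby(["run", "block", "cue_value", "unit"],
                               observed=True)
               [["first_trial", "early", "late"]].mean().reset_index())
    wide = per_run.pivot_table(index=["run", "block", "unit"],
                               columns="cue_value",
                               values=["first_trial", "early", "late"])
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()
    for w in ("first_trial", "early", "late"):
        wide[f"{w}_contrast"] = wide[f"{w}_high"] - wide[f"{w}_low"]
    table = (wide.groupby(["block", "unit"], observed=True)
             [[c for c in wide.columns if c not in ("run", "block", "unit")]]
             .agg(["mean", "std"]))
    table.columns = ["_".join(c) for c in table.columns]
    return EventAlignedSummary(condition=result.condition, per_run=wide,
                               table=table.reset_index(), early_n=early_n,
                               late_n=late_n, n_runs=cfg.n_runs)


def compare_conditions(summary_a: EventAlignedSummary,
                       summary_b: EventAlignedSummary) -> pd.DataFrame:
    """Per-event difference and ratio of two summaries (a minus a/b over b)."""
    ta, tb = summary_a.table, summary_b.table
    keys = [c for c in ("tag", "block", "unit") if c in ta.columns]
    if keys != [c for c in ("tag", "block", "unit") if c in tb.columns]:
        raise SchemaError("summaries have different shapes")
    if set(map(tuple, ta[keys].to_numpy())) != set(map(tuple, tb[keys].to_numpy())):
        raise SchemaError("summaries cover different events")
    merged = ta.merge(tb, on=keys, suffixes=("_a", "_b"))
    for w in ("first_trial", "early", "late"):
        col = f"{w}_mean"
        if f"{col}_a" in merged:
            merged[f"{w}_diff"] = merged[f"{col}_a"] - merged[f"{col}_b"]
            denom = merged[f"{col}_b"].replace(0.0, np.nan)
            merged[f"{w}_ratio"] = merged[f"{col}_a"] / denom
    return merged
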