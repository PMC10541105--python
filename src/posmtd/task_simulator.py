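"""Discrete-time event streams for the four-block odor-guided choice task.

A session is four blocks of trials.  In blocks 1-2 the two fluid wells
differ in reward *timing* (one short delay of 0.5 s, one long delay titrated
from 1 s up to 7 s), with the sides swapped between the blocks; in blocks
3-4 the delay is held at 0.5 s on both sides while reward *number* differs
(one side delivers a second bolus 500 ms after the first), again swapped.
The side that is short in block 1 becomes long in block 2, big in block 3
and small in block 4 (side role "A"); the other side ("B") takes the
complementary roles.  Unexpected deliveries therefore occur at block 2 on
side B (previously long, now immediate) and at block 3 on side A (first
bolus now immediate, and the session's first second bolus); unexpected
omissions occur at block 2 on side A (no reward at the learned 0.5 s
latency) and at block 4 on side A (second bolus withheld).

Each trial is rendered on the dt grid as observation symbols: light-on,
odor (left/right), well entry, reward bolus(es), light-off, with empty
observations elsewhere and an inter-trial interval before the next light.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import TaskConfig
from .errors import ConfigurationError, SchedulingError
from .state_spaces import DEFAULT_ALPHABET

#: trial-type labels
FORCED_LEFT, FORCED_RIGHT, FREE = "forced_left", "forced_right", "free"

#: analysis event tags (see module docstring for the task logic behind them)
DELIVERY_TAGS = ("2sh_reward", "4bg_bolus2")
OMISSION_TAGS = ("2lo_omission", "4sm_omission")
BOLUS3_TAGS = ("3bg_bolus1", "3bg_bolus2")


@dataclass(frozen=True)
class SessionConfig:
    """Scheduling configuration for one session.

    ``task`` carries timing; ``include_free_choice`` keeps free-choice odors
    in the schedule (they are relabeled toward the currently higher-valued
    side before reaching the agent, mirroring the forced-trial
    simplification); ``side_a_is_left`` pins which physical side plays role
    A (None draws it from the seeded stream, as at the start of a recording
    session).
    """

    task: TaskConfig = field(default_factory=TaskConfig)
    include_free_choice: bool = False
    side_a_is_left: bool | None = None
    seed: int = 0

    @property
    def trials_per_block(self) -> int:
        return self.task.trials_per_block


@dataclass
class TrialObservationSequence:
    """One trial rendered on the time grid.

    ``symbols[i]`` is the observation index at step i (trial-relative);
    ``rewards[i]`` the bolus count delivered at that step.  ``event_times``
    maps event names to trial-relative steps; ``metadata['event_tags']``
    maps analysis tags to trial-relative steps (including expected-but-empty
    omission steps).  ``start_step`` is the trial's absolute offset in the
    session stream.
    """

    symbols: np.ndarray
    rewards: np.ndarray
    event_times: dict
    trial_type: str
    block: int
    trial_in_block: int
    start_step: int
    metadata: dict

    def __len__(self):
        return len(self.symbols)


@dataclass
class Session:
    config: SessionConfig
    trials: list
    lead_in_steps: int

    def concatenate(self):
        """(symbols, rewards) arrays for the whole session stream."""
        n = self.lead_in_steps + sum(len(tr) for tr in self.trials)
        null = DEFAULT_ALPHABET.null_index
        sym = np.full(n, null, dtype=np.int64)
        rew = np.zeros(n, dtype=float)
        for tr in self.trials:
            sym[tr.start_step:tr.start_step + len(tr)] = tr.symbols
            rew[tr.start_step:tr.start_step + len(tr)] = tr.rewards
        return sym, rew

    def event_table(self):
        """One row per tagged event: block, trial, tag, absolute step."""
        import pandas as pd

        rows = []
        for tr in self.trials:
            for tag, step in tr.metadata["event_tags"].items():
                rows.append({
                    "block": tr.block, "trial_in_block": tr.trial_in_block,
                    "trial_type": tr.trial_type,
                    "cue_value": tr.metadata["cue_value"],
                    "side_role": tr.metadata["side_role"],
                    "tag": tag, "step": tr.start_step + step,
                    "t_rel": step * self.config.task.dt,
                    "trial_start_step": tr.start_step,
                    "trial_len_s": len(tr) * self.config.task.dt,
                })
        return pd.DataFrame(rows)

    def to_frame(self):
        """Per-step long format (block, trial, t, symbol) for serialization."""
        import pandas as pd

        sym, _ = self.concatenate()
        block = np.zeros(len(sym), dtype=int)
        trial = np.zeros(len(sym), dtype=int)
        for tr in self.trials:
            block[tr.start_step:tr.start_step + len(tr)] = tr.block
            trial[tr.start_step:tr.start_step + len(tr)] = tr.trial_in_block
        return pd.DataFrame({
            "t": np.arange(len(sym)), "block": block, "trial": trial,
            "symbol": [DEFAULT_ALPHABET.symbols[i] for i in sym]})


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def long_delay_schedule(choice_history) -> float:
    """Delay (s) on the upcoming long-side trial given prior choices.

    ``choice_history`` lists, per prior choice trial, whether the long side
    was chosen.  The delay starts at 1 s and grows by 1 s with every
    long-side choice to a 7 s cap; whenever fewer than 8 of the last 10
    choice trials went long, it drops by 1 s toward a 3 s floor.
    """
    cfg = TaskConfig()
    delay = cfg.long_delay_initial
    window: list[bool] = []
    for chose_long in choice_history:
        if chose_long:
            delay = min(delay + cfg.long_delay_step, cfg.long_delay_max)
        window.append(bool(chose_long))
        if len(window) > 10:
            window.pop(0)
        if len(window) == 10 and sum(window) < 8:
            delay = max(delay - cfg.long_delay_step, cfg.long_delay_min)
    return delay


def _constrained_shuffle(rng, counts: dict, prev_run, max_run=3, retries=2000):
    """Arrange symbols with given counts so no run exceeds ``max_run``,
    continuing the run carried in from the previous window."""
    symbols = [s for s, c in counts.items() for _ in range(c)]
    for _ in range(retries):
        rng.shuffle(symbols)
        run_sym, run_len = prev_run
        ok = True
        for s in symbols:
            if s == run_sym:
                run_len += 1
                if run_len > max_run:
                    ok = False
                    break
            else:
                run_sym, run_len = s, 1
        if ok:
            return list(symbols), (run_sym, run_len)
    raise SchedulingError("could not satisfy run-length constraint")


def odor_schedule(n_trials: int, seed: int, include_free: bool = True) -> list:
    """Pseudorandom trial types: 7 free per 20-trial window (when enabled),
    equal forced-left/right counts over every 40-trial span, and no odor
    more than 3 trials in a row.  Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    n_windows = -(-n_trials // 20)
    out: list[str] = []
    prev_run = (None, 0)
    for w in range(n_windows):
        n_free = 7 if include_free else 0
        n_forced = 20 - n_free
        half = n_forced // 2
        # alternate the odd forced trial between sides so 40-trial spans balance
        if n_forced % 2:
            left = half + (1 if w % 2 == 0 else 0)
        else:
            left = half
        counts = {FORCED_LEFT: left, FORCED_RIGHT: n_forced - left}
        if n_free:
            counts[FREE] = n_free
        window, prev_run = _constrained_shuffle(rng, counts, prev_run)
        out.extend(window)
    return out[:n_trials]


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def _block_roles(block: int) -> dict:
    """side role -> (is_short_or_big_side, n_boluses handled later)."""
    return {
        1: {"A": "short", "B": "long"},
        2: {"A": "long", "B": "short"},
        3: {"A": "big", "B": "small"},
        4: {"A": "small", "B": "big"},
    }[block]


def _render_trial(cfg: TaskConfig, delay_s: float, n_boluses: int,
                  side: str, alphabet=DEFAULT_ALPHABET):
    """Symbols, rewards and event times for one trial (trial-relative)."""
    st = cfg.steps
    light_on = 0
    odor = light_on + st(cfg.light_to_odor)
    well = odor + st(cfg.odor_to_well)
    r1 = well + st(delay_s)
    events = {"light_on": light_on, "odor": odor, "well_entry": well,
              "reward_1": r1}
    last_reward = r1
    if n_boluses == 2:
        r2 = r1 + st(cfg.inter_bolus_gap)
        events["reward_2"] = r2
        last_reward = r2
    light_off = last_reward + st(cfg.reward_to_light_off)
    events["light_off"] = light_off
    n = light_off + st(cfg.iti_duration)
    sym = np.full(n, alphabet.null_index, dtype=np.int64)
    rew = np.zeros(n, dtype=float)
    sym[light_on] = alphabet.index("light_on")
    sym[odor] = alphabet.index("odor_left" if side == "left" else "odor_right")
    sym[well] = alphabet.index("well_entry")
    sym[r1] = alphabet.index("reward")
    rew[r1] = 1.0
    if n_boluses == 2:
        sym[events["reward_2"]] = alphabet.index("reward")
        rew[events["reward_2"]] = 1.0
    sym[light_off] = alphabet.index("light_off")
    return sym, rew, events


def generate_session(config: SessionConfig) -> Session:
    """Generate one full session (4 blocks) of trial observation streams."""
    cfg = config.task
    rng = np.random.default_rng(config.seed)
    if config.side_a_is_left is None:
        side_a = "left" if rng.random() < 0.5 else "right"
    else:
        side_a = "left" if config.side_a_is_left else "right"
    side_of = {"A": side_a, "B": "right" if side_a == "left" else "left"}
    role_of_side = {v: k for k, v in side_of.items()}

    trials: list[TrialObservationSequence] = []
    lead_in = cfg.steps(cfg.iti_duration)
    step = lead_in
    for block in (1, 2, 3, 4):
        roles = _block_roles(block)
        types = odor_schedule(config.trials_per_block,
                              int(rng.integers(2 ** 31)),
                              include_free=config.include_free_choice)
        long_choices: list[bool] = []
        for i, ttype in enumerate(types):
            original_type = ttype
            if ttype == FREE:
                # free-choice simplification: treat as a forced trial toward
                # the currently higher-valued side
                high_role = "A" if roles["A"] in ("short", "big") else "B"
                ttype = (FORCED_LEFT if side_of[high_role] == "left"
                         else FORCED_RIGHT)
            side = "left" if ttype == FORCED_LEFT else "right"
            role = role_of_side[side]
            contingency = roles[role]
            if contingency == "long":
                if cfg.fixed_long_delay is not None:
                    delay = cfg.fixed_long_delay
                else:
                    delay = long_delay_schedule(long_choices)
                long_choices.append(True)
                n_boluses = 1
            elif contingency == "short":
                delay = cfg.short_delay
                n_boluses = 1
            else:
                delay = cfg.short_delay
                n_boluses = 2 if contingency == "big" else 1
            sym, rew, events = _render_trial(cfg, delay, n_boluses, side)

            high_contingency = ("short", "big")
            cue_value = "high" if contingency in high_contingency else "low"
            tags = {"cue": events["odor"], "reward1": events["reward_1"]}
            if block == 2 and contingency == "short":
                tags["2sh_reward"] = events["reward_1"]
            if block == 2 and contingency == "long":
                tags["2lo_omission"] = events["well_entry"] + cfg.short_delay_steps
            if block == 3 and contingency == "big":
                tags["3bg_bolus1"] = events["reward_1"]
                tags["3bg_bolus2"] = events["reward_2"]
            if block == 4 and contingency == "big":
                tags["4bg_bolus2"] = events["reward_2"]
            if block == 4 and contingency == "small":
                tags["4sm_omission"] = events["reward_1"] + cfg.steps(cfg.inter_bolus_gap)

            trials.append(TrialObservationSequence(
                symbols=sym, rewards=rew, event_times=events,
                trial_type=ttype, block=block, trial_in_block=i + 1,
                start_step=step,
                metadata={
                    "original_type": original_type,
                    "side": side, "side_role": role,
                    "contingency": contingency, "delay_s": delay,
                    "n_boluses": n_boluses, "cue_value": cue_value,
                    "omission": contingency in ("long",) and block == 2
                                or contingency == "small" and block == 4,
                    "event_tags": tags,
                },
            ))
            step += len(sym)
    return Session(config=config, trials=trials, lead_in_steps=lead_in)


def generate_stationary_session(task: TaskConfig | None = None, *,
                                n_trials: int = 100, delay_s: float = 0.5,
                                n_boluses: int = 1, seed: int = 0) -> Session:
    """A stationary control environment: every trial has the same reward
    contingency on both sides (forced left/right at random).  Used for
    convergence checks where no block structure should drive errors."""
    cfg = task or TaskConfig()
    rng = np.random.default_rng(seed)
    trials = []
    lead_in = cfg.steps(cfg.iti_duration)
    step = lead_in
    for i in range(n_trials):
        side = "left" if rng.random() < 0.5 else "right"
        sym, rew, events = _render_trial(cfg, delay_s, n_boluses, side)
        trials.append(TrialObservationSequence(
            symbols=sym, rewards=rew, event_times=events,
            trial_type=FORCED_LEFT if side == "left" else FORCED_RIGHT,
            block=1, trial_in_block=i + 1, start_step=step,
            metadata={"side": side, "side_role": "A", "contingency": "short",
                      "delay_s": delay_s, "n_boluses": n_boluses,
                      "cue_value": "high", "omission": False,
                      "original_type": "forced",
                      "event_tags": {"cue": events["odor"],
                                     "reward1": events["reward_1"]}},
        ))
        step += len(sym)
    return Session(config=SessionConfig(task=cfg, seed=seed), trials=trials,
                   lead_in_steps=lead_in)


def parse_event_times(trial: TrialObservationSequence,
                      alphabet=DEFAULT_ALPHABET) -> dict:
    """Recover event times from a trial's symbol stream (round-trip check)."""
    sym = trial.symbols
    out = {}
    for i, s in enumerate(sym):
        name = alphabet.symbols[s]
        if name == "null":
            continue
        if name == "light_on":
            out["light_on"] = i
        elif name in ("odor_left", "odor_right"):
            out["odor"] = i
        elif name == "well_entry":
            out["well_entry"] = i
        elif name == "reward":
            out.setdefault("reward_1", i)
            if "reward_1" in out and i != out["reward_1"]:
                out["reward_2"] = i
        elif name == "light_off":
            out["light_off"] = i
    return out
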