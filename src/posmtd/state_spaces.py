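"""Task state spaces for the odor-guided choice task.

Two generative task maps are built here:

* **Model 1** — a flat space mirroring the animal's physical situation within
  a trial: trial start, left/right cue, left/right well, two reward states
  per side, and the inter-trial interval (ten states).  Dwell distributions
  are plastic and are learned from experience.

* **Model 2** — a hierarchical space in which an upper level (the inter-trial
  state plus one trial-start state per block) controls which block's
  lower-level trial subgraph is entered.  Each block has its own copies of
  the within-trial states carrying that block's reward contingency, so dwell
  distributions are fixed at the task's mean event latencies and only the
  inter-trial -> trial-start transition row is plastic.

Simulated hippocampal lesions are expressed purely as transforms of the
transition structure: Model 1 blurs the cue -> well transitions
(0.55 same side / 0.45 opposite), Model 2 imposes a floor of 0.15 on the
upper-level transition row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .config import TaskConfig
from .errors import ConfigurationError, DegenerateInputError, InvalidModelError

ROW_TOL = 1e-9

#: lesion floor on the Model 2 upper-level transition row
MODEL2_LESION_FLOOR = 0.15
#: Model 1 lesion: cue -> same-side well / cue -> opposite well
MODEL1_LESION_SAME = 0.55
MODEL1_LESION_OPPOSITE = 0.45


@dataclass(frozen=True)
class ObservationAlphabet:
    """Ordered observation symbols with a designated empty (null) symbol."""

    symbols: tuple[str, ...]
    null_symbol: str = "null"

    def __post_init__(self):
        if self.symbols.count(self.null_symbol) != 1:
            raise ConfigurationError("alphabet must contain exactly one null symbol")

    @property
    def null_index(self) -> int:
        return self.symbols.index(self.null_symbol)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def __len__(self) -> int:
        return len(self.symbols)


#: Task events observable by the agent.  Wells are externally identical, so a
#: single side-agnostic well-entry event marks arrival at either well;
#: likewise a single reward symbol marks every bolus.
DEFAULT_ALPHABET = ObservationAlphabet(
    symbols=(
        "light_on",
        "odor_left",
        "odor_right",
        "well_entry",
        "reward",
        "light_off",
        "null",
    )
)


@dataclass(frozen=True)
class DwellKernelParams:
    """Parameters of the discretized Gaussian dwell kernel.

    ``cv_d`` is the coefficient of variation (s.d. = cv_d * mean), ``d_b``
    the per-grid-point probability floor, ``d_max`` the longest representable
    dwell and ``dt`` the grid step (both seconds).
    """

    cv_d: float = 0.05
    d_b: float = 1e-4
    d_max: float = 15.0
    dt: float = 0.1

    def __post_init__(self):
        if self.cv_d <= 0 or self.d_b <= 0 or self.d_max <= 0 or self.dt <= 0:
            raise ConfigurationError("dwell kernel parameters must be positive")
        if abs(self.d_max / self.dt - round(self.d_max / self.dt)) > 1e-9:
            raise ConfigurationError("d_max must be a positive multiple of dt")
        if self.d_b * self.n_steps >= 1.0:
            raise ConfigurationError("floor mass d_b * n_steps must be < 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.d_max / self.dt))

    @classmethod
    def from_task(cls, cfg: TaskConfig) -> "DwellKernelParams":
        return cls(cv_d=cfg.cv_d, d_b=cfg.baseline_dwell_prob, d_max=cfg.d_max, dt=cfg.dt)


def gaussian_dwell_kernel(mean_steps: float, kp: DwellKernelParams) -> np.ndarray:
    """Discretized Gaussian dwell kernel with a uniform probability floor.

    The kernel is a Gaussian density with mean ``mean_steps * dt`` and s.d.
    ``cv_d * mean``, evaluated on the grid d = dt, 2*dt, ..., d_max,
    normalized, and mixed with the uniform floor as
    ``d_b + (1 - n*d_b) * q``.  The mixture keeps every grid point at or
    above the floor d_b while summing exactly to 1, so convex dwell updates
    preserve both properties with no post-hoc repair.
    """
    n = kp.n_steps
    d = np.arange(1, n + 1, dtype=float) * kp.dt
    mu = float(mean_steps) * kp.dt
    sd = max(kp.cv_d * mu, 1e-12)
    w = np.exp(-0.5 * ((d - mu) / sd) ** 2)
    total = w.sum()
    if total <= 0.0:  # kernel narrower than the grid and centred off-grid
        w = np.zeros(n)
        w[int(np.clip(round(mean_steps) - 1, 0, n - 1))] = 1.0
        total = 1.0
    q = w / total
    return kp.d_b + (1.0 - n * kp.d_b) * q


def normalize_observation_row(raw_row) -> np.ndarray:
    """Normalize a nonnegative emission row to a probability vector."""
    row = np.asarray(raw_row, dtype=float)
    if np.any(row < 0):
        raise DegenerateInputError("observation row has negative entries")
    s = row.sum()
    if s <= 0:
        raise DegenerateInputError("observation row is all zero")
    return row / s


def floor_stochastic_row(row, floor: float) -> np.ndarray:
    """Raise every entry of a probability row to ``floor`` and renormalize."""
    row = np.asarray(row, dtype=float)
    return normalize_observation_row(np.maximum(row, floor))


@dataclass(frozen=True)
class StateSpace:
    """A semi-Markov task map: states, transitions, emissions and dwells.

    ``T[i, j]`` is P(next state j | leaving state i); ``O[i, m]`` is
    P(observation m | entering state i); ``D[i, k]`` is P(dwell = (k+1) * dt
    steps | state i).  ``level`` tags each state lower/upper (Model 2);
    ``plastic_transitions`` lists (source, target) label pairs whose
    probabilities are updated during learning.
    """

    state_labels: tuple[str, ...]
    alphabet: ObservationAlphabet
    T: np.ndarray
    O: np.ndarray
    D: np.ndarray
    kernel: DwellKernelParams
    level: tuple[str, ...]
    plastic_transitions: frozenset = frozenset()
    model: int = 1
    lesioned: bool = False
    upper_row_floor: float | None = None
    dwell_plastic: bool = True
    initial_state: str = "iti"
    block_states: dict | None = None          # model 2: block -> tuple of labels
    trial_start_states: tuple[str, ...] = ()  # model 2: upper-level ts labels
    meta: dict = field(default_factory=dict)

    # -- indexing -----------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def index(self, label: str) -> int:
        return self.state_labels.index(label)

    @property
    def initial_index(self) -> int:
        return self.index(self.initial_state)

    def survival(self) -> np.ndarray:
        """S[s, k] = P(dwell >= (k+1) * dt | s) (inclusive survival)."""
        return dwell_survival(self.D)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        S, M, n = self.n_states, len(self.alphabet), self.kernel.n_steps
        if self.T.shape != (S, S) or self.O.shape != (S, M) or self.D.shape != (S, n):
            raise ConfigurationError("matrix shapes inconsistent with labels/alphabet/grid")
        for name, mat in (("T", self.T), ("O", self.O), ("D", self.D)):
            if np.any(mat < 0):
                raise ConfigurationError(f"{name} has negative entries")
            if np.max(np.abs(mat.sum(axis=1) - 1.0)) > ROW_TOL:
                raise ConfigurationError(f"rows of {name} do not sum to 1")
        if np.min(self.D) < self.kernel.d_b - 1e-12:
            raise ConfigurationError("dwell distribution below floor d_b")
        if self.model == 1 and any(lv == "upper" for lv in self.level):
            raise ConfigurationError("Model 1 must not contain upper-level states")
        if self.model == 2:
            uppers = [l for l, lv in zip(self.state_labels, self.level) if lv == "upper"]
            expected = set(self.trial_start_states) | {self.initial_state}
            if set(uppers) != expected:
                raise ConfigurationError(
                    "Model 2 upper level must be the inter-trial state plus one "
                    "trial-start state per block"
                )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "state_labels": list(self.state_labels),
            "alphabet": {"symbols": list(self.alphabet.symbols),
                         "null_symbol": self.alphabet.null_symbol},
            "T": self.T.tolist(),
            "O": self.O.tolist(),
            "D": self.D.tolist(),
            "kernel": {"cv_d": self.kernel.cv_d, "d_b": self.kernel.d_b,
                       "d_max": self.kernel.d_max, "dt": self.kernel.dt},
            "level": list(self.level),
            "plastic_transitions": sorted(self.plastic_transitions),
            "model": self.model,
            "lesioned": self.lesioned,
            "upper_row_floor": self.upper_row_floor,
            "dwell_plastic": self.dwell_plastic,
            "initial_state": self.initial_state,
            "block_states": ({str(k): list(v) for k, v in self.block_states.items()}
                             if self.block_states is not None else None),
            "trial_start_states": list(self.trial_start_states),
            "meta": self.meta,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StateSpace":
        return cls(
            state_labels=tuple(d["state_labels"]),
            alphabet=ObservationAlphabet(tuple(d["alphabet"]["symbols"]),
                                         d["alphabet"]["null_symbol"]),
            T=np.array(d["T"], dtype=float),
            O=np.array(d["O"], dtype=float),
            D=np.array(d["D"], dtype=float),
            kernel=DwellKernelParams(**d["kernel"]),
            level=tuple(d["level"]),
            plastic_transitions=frozenset(tuple(p) for p in d["plastic_transitions"]),
            model=d["model"],
            lesioned=d["lesioned"],
            upper_row_floor=d["upper_row_floor"],
            dwell_plastic=d["dwell_plastic"],
            initial_state=d["initial_state"],
            block_states=({int(k): tuple(v) for k, v in d["block_states"].items()}
                          if d["block_states"] is not None else None),
            trial_start_states=tuple(d["trial_start_states"]),
            meta=d["meta"],
        )

    @classmethod
    def from_json(cls, text_or_path: str) -> "StateSpace":
        text = text_or_path
        if "\n" not in text and text.strip().endswith(".json"):
            with open(text_or_path) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))


def dwell_survival(D: np.ndarray) -> np.ndarray:
    """Inclusive survival S[s, k] = P(dwell >= (k+1) steps)."""
    return np.cumsum(D[:, ::-1], axis=1)[:, ::-1]


# ---------------------------------------------------------------------------
# emission rows
# ---------------------------------------------------------------------------

def _emission_row(alphabet: ObservationAlphabet, characteristic: str,
                  cfg: TaskConfig) -> np.ndarray:
    """0.95 characteristic / 0.05 null / 1e-4 each remaining symbol, normalized."""
    raw = np.full(len(alphabet), cfg.background_emission)
    raw[alphabet.index(characteristic)] = cfg.characteristic_emission
    raw[alphabet.null_index] = cfg.null_emission
    return normalize_observation_row(raw)


MODEL1_STATES = (
    "trial_start",
    "left_cue", "right_cue",
    "left_well", "right_well",
    "left_reward_1", "left_reward_2",
    "right_reward_1", "right_reward_2",
    "iti",
)

_MODEL1_CHARACTERISTIC = {
    "trial_start": "light_on",
    "left_cue": "odor_left",
    "right_cue": "odor_right",
    "left_well": "well_entry",
    "right_well": "well_entry",
    "left_reward_1": "reward",
    "left_reward_2": "reward",
    "right_reward_1": "reward",
    "right_reward_2": "reward",
    "iti": "light_off",
}


# ---------------------------------------------------------------------------
# Model 1
# ---------------------------------------------------------------------------

def build_model1(task_config: TaskConfig | None = None, *,
                 cue_to_same_well: float = 1.0,
                 cue_to_opposite_well: float | None = None) -> StateSpace:
    """Flat within-trial task space (control variant by default).

    The transition graph follows the trial's physical course: the inter-trial
    state leads to trial start (light onset), which branches to either cue;
    each cue leads to the same-side well (probability ``cue_to_same_well``,
    remainder to the opposite well); each well leads to that side's first
    reward state, which continues to the second reward state or back to the
    inter-trial state (either continuation occurs in the task, so both carry
    probability 0.5).  Initial dwell distributions are Gaussian kernels at the
    task's nominal event latencies; they are plastic and relearned online.
    """
    cfg = task_config or TaskConfig()
    if not (0.0 <= cue_to_same_well <= 1.0):
        raise ConfigurationError("cue_to_same_well must be in [0, 1]")
    if cue_to_opposite_well is None:
        cue_to_opposite_well = 1.0 - cue_to_same_well
    if abs(cue_to_same_well + cue_to_opposite_well - 1.0) > ROW_TOL:
        raise ConfigurationError("cue transition probabilities must sum to 1")
    alphabet = DEFAULT_ALPHABET
    kp = DwellKernelParams.from_task(cfg)
    labels = MODEL1_STATES
    S = len(labels)
    idx = {l: i for i, l in enumerate(labels)}

    T = np.zeros((S, S))
    T[idx["iti"], idx["trial_start"]] = 1.0
    T[idx["trial_start"], idx["left_cue"]] = 0.5
    T[idx["trial_start"], idx["right_cue"]] = 0.5
    T[idx["left_cue"], idx["left_well"]] = cue_to_same_well
    T[idx["left_cue"], idx["right_well"]] = cue_to_opposite_well
    T[idx["right_cue"], idx["right_well"]] = cue_to_same_well
    T[idx["right_cue"], idx["left_well"]] = cue_to_opposite_well
    T[idx["left_well"], idx["left_reward_1"]] = 1.0
    T[idx["right_well"], idx["right_reward_1"]] = 1.0
    T[idx["left_reward_1"], idx["left_reward_2"]] = 0.5
    T[idx["left_reward_1"], idx["iti"]] = 0.5
    T[idx["right_reward_1"], idx["right_reward_2"]] = 0.5
    T[idx["right_reward_1"], idx["iti"]] = 0.5
    T[idx["left_reward_2"], idx["iti"]] = 1.0
    T[idx["right_reward_2"], idx["iti"]] = 1.0

    O = np.vstack([_emission_row(alphabet, _MODEL1_CHARACTERISTIC[l], cfg) for l in labels])

    mean_steps = {
        "trial_start": cfg.steps(cfg.light_to_odor),
        "left_cue": cfg.steps(cfg.odor_to_well),
        "right_cue": cfg.steps(cfg.odor_to_well),
        "left_well": cfg.steps(1.0),
        "right_well": cfg.steps(1.0),
        "left_reward_1": cfg.steps(1.0),
        "left_reward_2": cfg.steps(1.0),
        "right_reward_1": cfg.steps(1.0),
        "right_reward_2": cfg.steps(1.0),
        "iti": cfg.steps(cfg.iti_duration),
    }
    D = np.vstack([gaussian_dwell_kernel(mean_steps[l], kp) for l in labels])

    space = StateSpace(
        state_labels=labels, alphabet=alphabet, T=T, O=O, D=D, kernel=kp,
        level=tuple("lower" for _ in labels),
        plastic_transitions=frozenset(), model=1,
        lesioned=(cue_to_same_well != 1.0),
        dwell_plastic=True, initial_state="iti",
        meta={"characteristic_obs": dict(_MODEL1_CHARACTERISTIC),
              "cue_to_same_well": cue_to_same_well},
    )
    space.validate()
    return space


def build_model1_lesioned(task_config: TaskConfig | None = None) -> StateSpace:
    """Model 1 with blurred cue -> well transitions (0.55 same / 0.45 opposite)."""
    return build_model1(task_config, cue_to_same_well=MODEL1_LESION_SAME,
                        cue_to_opposite_well=MODEL1_LESION_OPPOSITE)


# ---------------------------------------------------------------------------
# Model 2
# ---------------------------------------------------------------------------

def _block_contingencies(cfg: TaskConfig) -> dict:
    """Per-block (delay_steps, n_boluses) for each side, canonical patterns.

    Block 1: left short / right long; block 2 swapped.  Block 3: left big
    (two boluses) / right small; block 4 swapped.  Delays in number blocks
    equal the short delay.  (Which physical side plays which role in a given
    session is decided by the simulator; the four patterns cover both
    assignments because a side swap simply permutes the block order.)
    """
    short = cfg.short_delay_steps
    long_mean = cfg.steps(cfg.long_delay_mean())
    return {
        1: {"left": (short, 1), "right": (long_mean, 1)},
        2: {"left": (long_mean, 1), "right": (short, 1)},
        3: {"left": (short, 2), "right": (short, 1)},
        4: {"left": (short, 1), "right": (short, 2)},
    }


def build_model2(task_config: TaskConfig | None = None) -> StateSpace:
    """Hierarchical task space: per-block trial subgraphs under an upper level.

    The upper level is the shared inter-trial state plus one trial-start
    state per block; the inter-trial -> trial-start row is initialized
    uniform (0.25 each) and is the only plastic transition.  Each block's
    subgraph encodes that block's reward contingency exactly (deterministic
    lower-level transitions), and dwell distributions are fixed at the task's
    mean event latencies — differing reward timings live in separate states,
    so dwells need not be learned.
    """
    cfg = task_config or TaskConfig()
    alphabet = DEFAULT_ALPHABET
    kp = DwellKernelParams.from_task(cfg)
    contingencies = _block_contingencies(cfg)
    if set(contingencies) != {1, 2, 3, 4}:
        raise ConfigurationError("model 2 requires contingencies for blocks 1-4")

    labels: list[str] = []
    level: list[str] = []
    char: dict[str, str] = {}
    mean_steps: dict[str, float] = {}
    block_states: dict[int, tuple[str, ...]] = {}
    ts_states: list[str] = []

    def add(label, lev, obs, dwell_steps):
        labels.append(label)
        level.append(lev)
        char[label] = obs
        mean_steps[label] = dwell_steps

    for b in (1, 2, 3, 4):
        members = []

        def addb(label, lev, obs, dwell):
            add(label, lev, obs, dwell)
            members.append(label)

        ts = f"b{b}_trial_start"
        addb(ts, "upper", "light_on", cfg.steps(cfg.light_to_odor))
        ts_states.append(ts)
        for side in ("left", "right"):
            delay, n_bolus = contingencies[b][side]
            odor = f"odor_{side}"
            addb(f"b{b}_{side}_cue", "lower", odor, cfg.steps(cfg.odor_to_well))
            addb(f"b{b}_{side}_well", "lower", "well_entry", delay)
            r1_dwell = (cfg.steps(cfg.inter_bolus_gap) if n_bolus == 2
                        else cfg.steps(cfg.reward_to_light_off))
            addb(f"b{b}_{side}_reward_1", "lower", "reward", r1_dwell)
            if n_bolus == 2:
                addb(f"b{b}_{side}_reward_2", "lower", "reward",
                     cfg.steps(cfg.reward_to_light_off))
        block_states[b] = tuple(members)

    add("iti", "upper", "light_off", cfg.steps(cfg.iti_duration))

    S = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    T = np.zeros((S, S))
    for b in (1, 2, 3, 4):
        T[idx["iti"], idx[f"b{b}_trial_start"]] = 0.25
        for side in ("left", "right"):
            _, n_bolus = contingencies[b][side]
            T[idx[f"b{b}_trial_start"], idx[f"b{b}_{side}_cue"]] = 0.5
            T[idx[f"b{b}_{side}_cue"], idx[f"b{b}_{side}_well"]] = 1.0
            T[idx[f"b{b}_{side}_well"], idx[f"b{b}_{side}_reward_1"]] = 1.0
            if n_bolus == 2:
                T[idx[f"b{b}_{side}_reward_1"], idx[f"b{b}_{side}_reward_2"]] = 1.0
                T[idx[f"b{b}_{side}_reward_2"], idx["iti"]] = 1.0
            else:
                T[idx[f"b{b}_{side}_reward_1"], idx["iti"]] = 1.0

    O = np.vstack([_emission_row(alphabet, char[l], cfg) for l in labels])
    D = np.vstack([gaussian_dwell_kernel(mean_steps[l], kp) for l in labels])

    space = StateSpace(
        state_labels=tuple(labels), alphabet=alphabet, T=T, O=O, D=D, kernel=kp,
        level=tuple(level),
        plastic_transitions=frozenset(("iti", ts) for ts in ts_states),
        model=2, lesioned=False, upper_row_floor=None, dwell_plastic=False,
        initial_state="iti",
        block_states=block_states, trial_start_states=tuple(ts_states),
        meta={"characteristic_obs": char, "dwell_mean_steps": mean_steps,
              "contingencies": {str(b): {s: list(v) for s, v in c.items()}
                                for b, c in contingencies.items()}},
    )
    space.validate()
    return space


def apply_model2_lesion(space: StateSpace,
                        floor: float = MODEL2_LESION_FLOOR) -> StateSpace:
    """Impose an uncertainty floor on the upper-level transition row.

    Every inter-trial -> trial-start probability below ``floor`` is raised to
    it and the row renormalized; the floor is carried on the returned space
    and reapplied after every learning update of the row.  Applying the
    transform to an already-lesioned space is a no-op (idempotent).
    """
    if space.model != 2:
        raise InvalidModelError("upper-level lesion applies to Model 2 spaces only")
    if space.lesioned and space.upper_row_floor == floor:
        return space
    i = space.initial_index
    cols = [space.index(ts) for ts in space.trial_start_states]
    T = space.T.copy()
    T[i, cols] = floor_stochastic_row(T[i, cols], floor)
    return replace(space, T=T, lesioned=True, upper_row_floor=floor)
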