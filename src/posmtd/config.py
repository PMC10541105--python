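"""Task and model configuration.

A single :class:`TaskConfig` carries the time grid, the event timing of the
odor-guided choice task, and the emission/dwell parameters shared by the
state-space builders and the session simulator.  All defaults are the values
used throughout the study conditions; any of them can be overridden
programmatically or loaded from a YAML file with ``[task] / [model] /
[lesion] / [learning]`` sections via :func:`load_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class TaskConfig:
    """Timing and emission parameters of the four-block choice task.

    Times are in seconds; the discrete grid has step ``dt``.
    """

    # time grid
    dt: float = 0.1
    d_max: float = 15.0          # longest representable dwell
    # dwell kernel
    cv_d: float = 0.05           # coefficient of variation of dwell kernels
    baseline_dwell_prob: float = 1e-4   # probability floor D_b per grid point
    # within-trial event latencies
    light_to_odor: float = 1.0
    odor_to_well: float = 1.0
    short_delay: float = 0.5
    inter_bolus_gap: float = 0.5
    reward_to_light_off: float = 1.0
    iti_duration: float = 4.0
    # long-delay titration
    long_delay_initial: float = 1.0
    long_delay_step: float = 1.0
    long_delay_max: float = 7.0
    long_delay_min: float = 3.0
    # block structure
    trials_per_block: int = 65
    # observation emissions
    characteristic_emission: float = 0.95
    null_emission: float = 0.05
    background_emission: float = 1e-4
    # optional static long delay (used e.g. for fixed-dwell variants)
    fixed_long_delay: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.d_max <= 0 or self.steps(self.d_max) < 1:
            raise ConfigurationError(f"d_max must be a positive multiple of dt, got {self.d_max}")
        if abs(self.d_max / self.dt - round(self.d_max / self.dt)) > 1e-9:
            raise ConfigurationError("d_max must be a multiple of dt")
        if self.cv_d <= 0:
            raise ConfigurationError("cv_d must be > 0")
        if self.baseline_dwell_prob <= 0:
            raise ConfigurationError("baseline_dwell_prob must be > 0")
        if self.baseline_dwell_prob * self.n_dwell_steps >= 1.0:
            raise ConfigurationError("dwell floor mass exceeds 1; lower baseline_dwell_prob")

    @property
    def n_dwell_steps(self) -> int:
        return int(round(self.d_max / self.dt))

    def steps(self, seconds: float) -> int:
        """Convert a latency in seconds to grid steps (rounded)."""
        return int(round(seconds / self.dt))

    @property
    def short_delay_steps(self) -> int:
        return self.steps(self.short_delay)

    def long_delay_mean(self) -> float:
        """Mean long delay (s) over a block under the deterministic titration.

        With choices clamped to the rewarded well every forced-long trial
        counts as a long-side choice, so the delay ramps
        1, 2, ..., long_delay_max and then stays at the cap.  The mean is
        taken over the forced-long trials of one block (roughly half the
        block).
        """
        if self.fixed_long_delay is not None:
            return self.fixed_long_delay
        n_long = max(1, self.trials_per_block // 2)
        delay = self.long_delay_initial
        total = 0.0
        for _ in range(n_long):
            total += delay
            delay = min(delay + self.long_delay_step, self.long_delay_max)
        return total / n_long


def _dataclass_from_mapping(cls, mapping, what):
    names = {f.name for f in fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigurationError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path) -> dict:
    """Load a YAML configuration file with [task]/[model]/[lesion]/[learning].

    Returns a dict with keys ``task`` (:class:`TaskConfig`), ``model`` (int),
    ``lesion`` (bool) and ``learning`` (mapping of learning-rule overrides,
    passed to :class:`posmtd.td_learning.LearningParams`).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    task = _dataclass_from_mapping(TaskConfig, raw.get("task", {}) or {}, "task")
    model = int((raw.get("model", {}) or {}).get("model", 1))
    if model not in (1, 2):
        raise ConfigurationError(f"model must be 1 or 2, got {model}")
    lesion = bool((raw.get("lesion", {}) or {}).get("enabled", False))
    learning = raw.get("learning", {}) or {}
    return {"task": task, "model": model, "lesion": lesion, "learning": learning}


def with_overrides(cfg: TaskConfig, **kwargs) -> TaskConfig:
    return replace(cfg, **kwargs)
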