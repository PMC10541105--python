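"""Synthetic unit recordings with known ground truth.

Dopamine-like units fire at a baseline rate except in 400 ms event windows,
where the rate follows the prediction-error-to-firing map applied to a
simulated agent's event-aligned errors (multiplied by a per-unit lognormal
gain); spikes are homogeneous Poisson within each segment.  Non-dopaminergic
units fire at a PE-independent constant rate.  Waveform features are drawn
from two separable Gaussian clusters (dopaminergic units have the longer
spike half duration).  Each unit is assigned one (run, session) of the
source experiment, like real units recorded in different sessions.

The generator exists so the unit-analysis chain can be exercised end to end
with no recorded data; what it does *not* emulate (bursting, inter-unit
correlations, drift) is documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .experiment import ExperimentResult
from .neural_analysis import (UnitRecording, classify_units,
                              population_tests, score_population)
from .td_learning import FiringParams, firing_rate_from_pe

#: lead time (s) inserted before light onset so the inter-trial baseline
#: window lives inside the trial's spike timeline
PRE_TRIAL_S = 1.0


@dataclass(frozen=True)
class SyntheticPopulationConfig:
    n_dopamine: int = 60
    n_other: int = 40
    gain_jitter: float = 0.2          # s.d. of lognormal per-unit gain
    da_half_duration: tuple = (0.40, 0.04)   # ms (mean, sd)
    da_amp_ratio: tuple = (1.6, 0.15)
    other_half_duration: tuple = (0.18, 0.03)
    other_amp_ratio: tuple = (0.9, 0.12)
    other_rate_range: tuple = (1.0, 10.0)    # Hz, uniform
    window: tuple = (0.1, 0.5)               # s after event
    firing: FiringParams = field(default_factory=FiringParams)
    seed: int = 0


def _source_records(pe_source) -> pd.DataFrame:
    if isinstance(pe_source, ExperimentResult):
        rec = pe_source.post_burn_in()
    elif isinstance(pe_source, pd.DataFrame):
        rec = pe_source
    else:
        raise SchemaError("pe_source must be an ExperimentResult or records frame")
    needed = {"run", "session", "block", "trial_in_block", "event_tag",
              "cue_value", "t_rel", "trial_len_s", "total_delta"}
    missing = needed - set(rec.columns)
    if missing:
        raise SchemaError(f"pe_source records missing columns {sorted(missing)}")
    if len(rec) == 0:
        raise SchemaError("pe_source has no post-burn-in records")
    return rec


def _poisson_segment(rng, rate, start, stop, out):
    if stop <= start or rate <= 0:
        return
    n = rng.poisson(rate * (stop - start))
    if n:
        out.append(rng.uniform(start, stop, size=n))


def _trial_spikes(rng, base_rate, windows, trial_len):
    """Piecewise-constant-rate Poisson spikes over [0, trial_len)."""
    pieces = []
    cursor = 0.0
    for w0, w1, rate in sorted(windows):
        w0, w1 = max(w0, 0.0), min(w1, trial_len)
        _poisson_segment(rng, base_rate, cursor, w0, pieces)
        _poisson_segment(rng, rate, w0, w1, pieces)
        cursor = max(cursor, w1)
    _poisson_segment(rng, base_rate, cursor, trial_len, pieces)
    if not pieces:
        return np.array([], dtype=float)
    return np.sort(np.concatenate(pieces))


def generate_population(config: SyntheticPopulationConfig, pe_source):
    """Generate synthetic units driven by an experiment's PE stream.

    Returns ``(units, ground_truth)``: a list of :class:`UnitRecording` and
    a table with each unit's true label, gain and source session.
    """
    rec = _source_records(pe_source)
    rng = np.random.default_rng(config.seed)
    fp = config.firing
    w0, w1 = config.window
    sessions = (rec[["run", "session"]].drop_duplicates()
                .sort_values(["run", "session"]).to_numpy())
    by_session = dict(tuple(rec.groupby(["run", "session"])))
    trial_cache: dict = {}

    def session_trials(key):
        """[(block, tib, cue_value, trial_len, [(tag, t_ev, delta), ...])]"""
        if key not in trial_cache:
            src = by_session[key]
            trials = []
            for (block, tib), g in src.groupby(["block", "trial_in_block"],
                                               sort=True):
                events = [(tag, PRE_TRIAL_S + float(t_rel), float(delta))
                          for tag, t_rel, delta in zip(
                              g["event_tag"].to_numpy(),
                              g["t_rel"].to_numpy(),
                              g["total_delta"].to_numpy())]
                trials.append((int(block), int(tib), g["cue_value"].iloc[0],
                               PRE_TRIAL_S + float(g["trial_len_s"].iloc[0]),
                               events))
            trial_cache[key] = trials
        return trial_cache[key]

    units, truth = [], []
    n_total = config.n_dopamine + config.n_other
    for i in range(n_total):
        is_da = i < config.n_dopamine
        run, session = sessions[int(rng.integers(len(sessions)))]
        gain = float(rng.lognormal(mean=0.0, sigma=config.gain_jitter))
        base_rate = (fp.baseline * gain if is_da else
                     float(rng.uniform(*config.other_rate_range)))
        if is_da:
            feats = (rng.normal(*config.da_half_duration),
                     rng.normal(*config.da_amp_ratio))
        else:
            feats = (rng.normal(*config.other_half_duration),
                     rng.normal(*config.other_amp_ratio))

        spikes, rows = [], []
        for trial_idx, (block, tib, cue_value, trial_len, events) in enumerate(
                session_trials((run, session))):
            row = {"trial": trial_idx, "block": block,
                   "trial_in_block": tib, "cue_value": cue_value,
                   "light_on": PRE_TRIAL_S,
                   "reward_time": np.nan, "delivery_time": np.nan,
                   "omission_time": np.nan, "cue_time": np.nan}
            windows = {}
            for tag, t_ev, delta in events:
                if tag == "reward1":
                    row["reward_time"] = t_ev
                elif tag in ("2sh_reward", "4bg_bolus2"):
                    row["delivery_time"] = t_ev
                elif tag in ("2lo_omission", "4sm_omission"):
                    row["omission_time"] = t_ev
                elif tag == "cue":
                    row["cue_time"] = t_ev
                rate = firing_rate_from_pe(fp, delta) * gain
                windows[t_ev] = (t_ev + w0, t_ev + w1, rate)
            if is_da:
                spikes.append(_trial_spikes(rng, base_rate,
                                            list(windows.values()), trial_len))
            else:
                spikes.append(_trial_spikes(rng, base_rate, [], trial_len))
            rows.append(row)

        uid = f"{'da' if is_da else 'other'}_{i:03d}"
        units.append(UnitRecording(
            unit_id=uid, spikes=spikes, waveform_features=feats,
            trial_table=pd.DataFrame(rows),
            metadata={"run": int(run), "session": int(session)}))
        truth.append({"unit_id": uid,
                      "label": "dopaminergic" if is_da else "other",
                      "gain": gain, "base_rate": base_rate,
                      "run": int(run), "session": int(session)})
    return units, pd.DataFrame(truth)


def generate_null_units(n_units: int, *, n_trials: int = 60,
                        rate_hz: float = 3.0, seed: int = 0) -> list:
    """Units whose reward-window and baseline rates are identical.

    Used to calibrate the false-positive rate of the reward-responsiveness
    test: under this null, a correctly calibrated one-sided test at level
    alpha flags a fraction alpha of units.
    """
    rng = np.random.default_rng(seed)
    units = []
    trial_len = 3.0
    rows = pd.DataFrame({
        "trial": np.arange(n_trials), "block": 1,
        "trial_in_block": np.arange(1, n_trials + 1),
        "light_on": PRE_TRIAL_S, "reward_time": PRE_TRIAL_S + 0.5,
    })
    for i in range(n_units):
        spikes = [_trial_spikes(rng, rate_hz, [], trial_len)
                  for _ in range(n_trials)]
        units.append(UnitRecording(
            unit_id=f"null_{i:04d}", spikes=spikes,
            waveform_features=(0.4, 1.6), trial_table=rows.copy()))
    return units


def parameter_recovery_suite(control_source, lesion_source,
                             config: SyntheticPopulationConfig | None = None,
                             *, seed: int = 0, early_n: int = 5,
                             late_n: int = 5, alpha: float = 0.05) -> dict:
    """Push control- and lesion-driven synthetic populations through the
    unit-analysis chain and report whether the qualitative population
    results are reproduced.

    Expected pattern: control delivery scores shifted above zero and
    omission scores below zero (signed-rank p < alpha); both shifts absent
    in the lesion-driven population (p > alpha); cue scores above zero in
    both.
    """
    config = config or SyntheticPopulationConfig()
    report = {"seed": seed, "alpha": alpha, "n_dopamine": config.n_dopamine}
    tables = {}
    for name, source, offset in (("control", control_source, 0),
                                 ("lesion", lesion_source, 1)):
        cfg = SyntheticPopulationConfig(
            **{**config.__dict__, "seed": seed * 2 + offset, "n_other": 0})
        units, _ = generate_population(cfg, source)
        table = score_population(units, early_n=early_n, late_n=late_n,
                                 window=config.window)
        tables[name] = table
        report[name] = population_tests(table, columns=(
            "delivery_score", "omission_score", "cue_score"))
    c, l = report["control"], report["lesion"]
    report["rank_sum"] = population_tests(
        tables["control"], tables["lesion"],
        columns=("delivery_score", "omission_score"))
    report["checks"] = {
        "control_delivery_positive": (c["delivery_score"]["mean"] > 0
                                      and c["delivery_score"]["signed_rank_p"] < alpha),
        "control_omission_negative": (c["omission_score"]["mean"] < 0
                                      and c["omission_score"]["signed_rank_p"] < alpha),
        "lesion_delivery_null": l["delivery_score"]["signed_rank_p"] > alpha,
        "lesion_omission_null": l["omission_score"]["signed_rank_p"] > alpha,
        "cue_positive_control": c["cue_score"]["mean"] > 0,
        "cue_positive_lesion": l["cue_score"]["mean"] > 0,
    }
    report["reproduced"] = all(report["checks"].values())
    return report
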