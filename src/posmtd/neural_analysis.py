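"""Unit-level analysis chain for (synthetic or real) VTA recordings.

The chain mirrors a standard dopamine-unit workflow: putative dopaminergic
units are identified from two waveform features (half duration of the spike
and the amplitude ratio of the first positive and negative segments) by a
leave-one-out cluster-assignment rule; units that significantly increase
firing to reward over an inter-trial baseline are kept as reward-responsive;
and learning-related dynamics are quantified by early-versus-late
*difference scores* per unit, tested at the population level with Wilcoxon
signed-rank (against zero) and rank-sum (between groups) statistics.

Spike data arrive as per-trial timestamp arrays plus a per-trial event
table; firing rates are spike counts over 400 ms windows divided by the
window length, with no smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegenerateClusterError, SchemaError, WindowingError)

#: analysis windows (s): event-locked window starts 100 ms after the event
EVENT_WINDOW = (0.1, 0.5)
#: baseline: 400 ms of the inter-trial interval ending at light onset
BASELINE_DURATION = 0.4


@dataclass
class UnitRecording:
    """Spikes and metadata for one unit.

    ``spikes[i]`` holds the trial-aligned spike times (s) of trial i;
    ``trial_table`` has one row per trial with at least columns ``trial``,
    ``block``, ``trial_in_block``, ``light_on`` and per-event time columns
    (``reward_time``, ``delivery_time``, ``omission_time``, ``cue_time``;
    NaN where the trial has no such event) plus ``cue_value``.
    """

    unit_id: str
    spikes: list
    waveform_features: tuple
    trial_table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"trial", "block", "trial_in_block", "light_on"}
        missing = required - set(self.trial_table.columns)
        if missing:
            raise SchemaError(f"trial_table missing columns {sorted(missing)}")

    def window_rate(self, trial: int, start: float, duration: float) -> float:
        ts = np.asarray(self.spikes[trial])
        return np.count_nonzero((ts >= start) & (ts < start + duration)) / duration


# ---------------------------------------------------------------------------
# waveform classification
# ---------------------------------------------------------------------------

def classify_units(features, *, n_clusters: int = 2, sd_threshold: float = 3.0,
                   mahalanobis: bool = False, seed: int = 0) -> list:
    """Leave-one-out cluster assignment of units in waveform-feature space.

    Features (n_units x 2: half duration in ms, amplitude ratio) are first
    clustered with seeded k-means (10 restarts, standardized features) to
    obtain provisional memberships.  Each unit is then assigned by the
    leave-one-out rule: the centre and s.d. of every cluster are recomputed
    without the unit, and the unit joins a cluster if it lies within
    ``sd_threshold`` standard deviations of its centre (per feature
    dimension by default; Mahalanobis distance optionally).  Units matching
    zero or more than one cluster are left unclassified.  The cluster with
    the longer mean half duration is labelled dopaminergic.

    Returns per-unit labels in {"dopaminergic", "other", "unclassified"}.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise SchemaError("features must be 2-D (units x features)")
    n = len(X)
    if n < 2 * n_clusters:
        raise SchemaError(f"need at least {2 * n_clusters} units")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(sd <= 0):
        raise DegenerateClusterError("a feature has zero variance")
    Z = (X - mu) / sd
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(Z)
    members = [np.flatnonzero(km.labels_ == c) for c in range(n_clusters)]

    qualifies = np.zeros((n, n_clusters), dtype=bool)
    for i in range(n):
        for c in range(n_clusters):
            others = members[c][members[c] != i]
            if len(others) < 2:
                continue
            centre = X[others].mean(axis=0)
            spread = X[others].std(axis=0, ddof=1)
            if np.any(spread <= 0):
                raise DegenerateClusterError(
                    f"cluster {c} has zero variance without unit {i}")
            if mahalanobis:
                cov = np.cov(X[others].T)
                try:
                    inv = np.linalg.inv(cov)
                except np.linalg.LinAlgError as exc:
                    raise DegenerateClusterError(str(exc)) from exc
                d2 = float((X[i] - centre) @ inv @ (X[i] - centre))
                qualifies[i, c] = d2 <= sd_threshold ** 2
            else:
                qualifies[i, c] = bool(
                    np.all(np.abs(X[i] - centre) <= sd_threshold * spread))

    # dopaminergic cluster: longer half duration (feature 0)
    half_means = [X[m][:, 0].mean() if len(m) else -np.inf for m in members]
    da_cluster = int(np.argmax(half_means))
    labels = []
    for i in range(n):
        hits = np.flatnonzero(qualifies[i])
        if len(hits) != 1:
            labels.append("unclassified")
        else:
            labels.append("dopaminergic" if hits[0] == da_cluster else "other")
    return labels


# ---------------------------------------------------------------------------
# reward responsiveness
# ---------------------------------------------------------------------------

def reward_responsiveness(unit: UnitRecording, *, alpha: float = 0.05,
                          window=EVENT_WINDOW,
                          baseline: str = "iti") -> tuple[bool, float]:
    """Paired one-sided test for increased firing to reward.

    Firing in the 400 ms window beginning 100 ms after reward delivery is
    compared, trial by trial, with a 400 ms baseline window: by default the
    inter-trial interval ending at light onset (``baseline="iti"``), or the
    400 ms immediately before reward (``baseline="pre_reward"``).  The unit
    is responsive iff firing increases on average and the paired one-sided
    t-test has p < alpha.
    """
    tt = unit.trial_table
    if "reward_time" not in tt.columns:
        raise SchemaError("trial_table has no reward_time column")
    rewarded = tt[np.isfinite(tt["reward_time"].to_numpy(dtype=float))]
    if len(rewarded) < 10:
        raise WindowingError("need at least 10 rewarded trials")
    ev, bl = [], []
    for i, r, lo in zip(rewarded["trial"].to_numpy(dtype=int),
                        rewarded["reward_time"].to_numpy(dtype=float),
                        rewarded["light_on"].to_numpy(dtype=float)):
        ev.append(unit.window_rate(i, r + window[0], window[1] - window[0]))
        if baseline == "pre_reward":
            bl.append(unit.window_rate(i, r - BASELINE_DURATION, BASELINE_DURATION))
        else:
            bl.append(unit.window_rate(i, lo - BASELINE_DURATION, BASELINE_DURATION))
    ev, bl = np.asarray(ev), np.asarray(bl)
    if np.all(ev == bl):
        return False, 1.0
    t, p = stats.ttest_rel(ev, bl, alternative="greater")
    if not np.isfinite(p):
        return False, 1.0
    return bool(p < alpha and ev.mean() > bl.mean()), float(p)


# ---------------------------------------------------------------------------
# difference scores
# ---------------------------------------------------------------------------

def _event_rates(unit: UnitRecording, time_col: str, window):
    tt = unit.trial_table
    if time_col not in tt.columns:
        raise SchemaError(f"trial_table has no {time_col} column")
    rows = tt[np.isfinite(tt[time_col].to_numpy(dtype=float))]
    cue_vals = (rows["cue_value"].to_numpy() if "cue_value" in rows.columns
                else np.full(len(rows), None))
    rates = []
    for b, tib, cv, i, t_ev in zip(rows["block"].to_numpy(dtype=int),
                                   rows["trial_in_block"].to_numpy(dtype=int),
                                   cue_vals,
                                   rows["trial"].to_numpy(dtype=int),
                                   rows[time_col].to_numpy(dtype=float)):
        rates.append((b, tib, cv,
                      unit.window_rate(i, t_ev + window[0],
                                       window[1] - window[0])))
    return pd.DataFrame(rates, columns=["block", "trial_in_block",
                                        "cue_value", "rate"])


def _early_late(df: pd.DataFrame, early_n: int, late_n: int):
    """Per-block early and late mean rates; NaN-free means across blocks."""
    earlies, lates = [], []
    for _, g in df.groupby("block"):
        g = g.sort_values("trial_in_block")
        if len(g) < early_n + late_n:
            raise WindowingError(
                f"only {len(g)} events in a block for {early_n}+{late_n} windows")
        r = g["rate"].to_numpy()
        earlies.append(r[:early_n].mean())
        lates.append(r[-late_n:].mean())
    return float(np.mean(earlies)), float(np.mean(lates))


def difference_scores(unit: UnitRecording, *, early_n: int = 5,
                      late_n: int = 5, window=EVENT_WINDOW) -> dict:
    """Early-vs-late difference scores for one unit (Hz).

    * ``delivery_score``  = mean firing on the first ``early_n`` unexpected
      reward deliveries minus the last ``late_n`` (per relevant block,
      averaged) — positive when the delivery response fades with learning;
    * ``omission_score``  = same contrast at expected-but-omitted reward
      times — negative when early suppression recovers;
    * ``cue_score``       = (high - low cue firing, late) minus (high - low,
      early) — positive when cue discrimination grows within blocks.
    """
    out = {"unit_id": unit.unit_id}
    for name, col in (("delivery_score", "delivery_time"),
                      ("omission_score", "omission_time")):
        df = _event_rates(unit, col, window)
        if len(df) == 0:
            out[name] = np.nan
            continue
        early, late = _early_late(df, early_n, late_n)
        out[name] = early - late
    cue = _event_rates(unit, "cue_time", window)
    if len(cue) == 0:
        out["cue_score"] = np.nan
        return out
    contrasts = {}
    for value, g in cue.groupby("cue_value"):
        contrasts[value] = _early_late(g, early_n, late_n)
    if not {"high", "low"} <= set(contrasts):
        out["cue_score"] = np.nan
        return out
    (eh, lh), (el, ll) = contrasts["high"], contrasts["low"]
    out["cue_score"] = (lh - ll) - (eh - el)
    return out


def score_population(units, **kwargs) -> pd.DataFrame:
    """Difference-score table (one row per unit)."""
    return pd.DataFrame([difference_scores(u, **kwargs) for u in units])


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ("delivery_score", "omission_score", "cue_score")


def _signed_rank(x: np.ndarray):
    x = x[np.isfinite(x)]
    x = x[x != 0.0]
    if len(x) == 0:
        return np.nan, 1.0
    res = stats.wilcoxon(x)
    return float(res.statistic), float(res.pvalue)


def population_tests(table: pd.DataFrame, other: pd.DataFrame | None = None,
                     columns=SCORE_COLUMNS) -> dict:
    """Wilcoxon signed-rank of each score column against zero, plus (when a
    second table is given) rank-sum tests between the two populations."""
    if len(table) < 6:
        raise SchemaError("need at least 6 units per group")
    out = {}
    for col in columns:
        if col not in table.columns:
            raise SchemaError(f"missing score column {col!r}")
        x = table[col].to_numpy(dtype=float)
        stat, p = _signed_rank(x)
        out[col] = {"n": int(np.sum(np.isfinite(x))),
                    "mean": float(np.nanmean(x)) if np.any(np.isfinite(x)) else np.nan,
                    "signed_rank_stat": stat, "signed_rank_p": p}
        if other is not None:
            y = other[col].to_numpy(dtype=float)
            x2, y2 = x[np.isfinite(x)], y[np.isfinite(y)]
            rs = stats.ranksums(x2, y2)
            out[col]["rank_sum_stat"] = float(rs.statistic)
            out[col]["rank_sum_p"] = float(rs.pvalue)
    return out


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def save_units(units, prefix) -> None:
    """Write spikes.csv / units.csv / trials.csv under a path prefix."""
    spike_rows, unit_rows, trial_frames = [], [], []
    for u in units:
        for i, ts in enumerate(u.spikes):
            for t in np.asarray(ts):
                spike_rows.append({"unit": u.unit_id, "trial": i,
                                   "timestamp": float(t)})
        unit_rows.append({"unit": u.unit_id,
                          "half_duration_ms": u.waveform_features[0],
                          "amplitude_ratio": u.waveform_features[1]})
        tt = u.trial_table.copy()
        tt.insert(0, "unit", u.unit_id)
        trial_frames.append(tt)
    pd.DataFrame(spike_rows).to_csv(f"{prefix}spikes.csv", index=False)
    pd.DataFrame(unit_rows).to_csv(f"{prefix}units.csv", index=False)
    pd.concat(trial_frames, ignore_index=True).to_csv(
        f"{prefix}trials.csv", index=False)


def load_units(prefix) -> list:
    """Inverse of :func:`save_units`."""
    spikes = pd.read_csv(f"{prefix}spikes.csv")
    units = pd.read_csv(f"{prefix}units.csv")
    trials = pd.read_csv(f"{prefix}trials.csv")
    out = []
    for _, row in units.iterrows():
        uid = row["unit"]
        tt = trials[trials["unit"] == uid].drop(columns=["unit"]).reset_index(drop=True)
        n_trials = int(tt["trial"].max()) + 1 if len(tt) else 0
        per_trial = [np.array([], dtype=float) for _ in range(n_trials)]
        mine = spikes[spikes["unit"] == uid]
        for trial, g in mine.groupby("trial"):
            per_trial[int(trial)] = np.sort(g["timestamp"].to_numpy(dtype=float))
        out.append(UnitRecording(
            unit_id=uid, spikes=per_trial,
            waveform_features=(float(row["half_duration_ms"]),
                               float(row["amplitude_ratio"])),
            trial_table=tt))
    return out
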