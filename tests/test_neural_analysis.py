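import numpy as np
import pandas as pd
import pytest

from posmtd import neural_analysis as na
from posmtd.errors import SchemaError, WindowingError


def make_unit(unit_id="u0", n_trials=40, *, base_spikes=2, delivery_extra=None,
              omission_missing=None, cue_extra=None, features=(0.4, 1.6)):
    """Deterministic unit: ``base_spikes`` spikes in every 400 ms analysis
    window; optional per-trial extra spikes in the delivery window (list
    indexed by occurrence) etc.  Events: light_on 1.0 s, cue 1.5 s,
    delivery/omission 3.0 s; two blocks of n_trials/2."""
    spikes, rows = [], []
    half = n_trials // 2
    for i in range(n_trials):
        block = 1 if i < half else 2
        tib = (i % half) + 1
        cue_value = "high" if i % 2 == 0 else "low"
        delivery = 3.0 if i % 2 == 0 else np.nan
        omission = 3.0 if i % 2 == 1 else np.nan
        occurrence = (tib - 1) // 2  # per-block occurrence index of the event type
        def window_train(t0, n):
            return t0 + 0.1 + 0.4 * (np.arange(n) + 0.5) / max(n, 1)
        train = [window_train(0.6 - 0.1, base_spikes),  # baseline before light
                 window_train(1.5, base_spikes
                              + (cue_extra[occurrence] if cue_extra and cue_value == "high" else 0))]
        if np.isfinite(delivery):
            n = base_spikes + (delivery_extra[occurrence] if delivery_extra else 0)
            train.append(window_train(3.0, n))
        else:
            n = base_spikes - (omission_missing[occurrence] if omission_missing else 0)
            train.append(window_train(3.0, max(n, 0)))
        spikes.append(np.sort(np.concatenate(train)))
        rows.append({"trial": i, "block": block, "trial_in_block": tib,
                     "light_on": 1.0, "cue_time": 1.5, "cue_value": cue_value,
                     "reward_time": delivery, "delivery_time": delivery,
                     "omission_time": omission})
    return na.UnitRecording(unit_id=unit_id, spikes=spikes,
                            waveform_features=features,
                            trial_table=pd.DataFrame(rows))


class TestClassifyUnits:
    @pytest.fixture
    def features(self):
        rng = np.random.default_rng(0)
        da = np.column_stack([rng.normal(0.40, 0.03, 30),
                              rng.normal(1.6, 0.1, 30)])
        other = np.column_stack([rng.normal(0.15, 0.02, 30),
                                 rng.normal(0.9, 0.08, 30)])
        return np.vstack([da, other])

    def test_well_separated_clusters_recovered(self, features):
        labels = na.classify_units(features, seed=0)
        assert labels[:30].count("dopaminergic") >= 28
        assert labels[30:].count("other") >= 28

    def test_center_unit_assigned(self, features):
        center = features[:30].mean(axis=0)
        labels = na.classify_units(np.vstack([features, center]), seed=0)
        assert labels[-1] == "dopaminergic"

    def test_far_outlier_unclassified(self, features):
        outlier = np.array([5.0, 30.0])
        labels = na.classify_units(np.vstack([features, outlier]), seed=0)
        assert labels[-1] == "unclassified"

    def test_between_cluster_unit_unclassified(self):
        # two tight clusters plus a unit within 3 s.d. of both
        rng = np.random.default_rng(1)
        a = np.column_stack([rng.normal(0.0, 1.0, 40), rng.normal(0.0, 1.0, 40)])
        b = np.column_stack([rng.normal(4.0, 1.0, 40), rng.normal(0.0, 1.0, 40)])
        mid = np.array([2.0, 0.0])
        labels = na.classify_units(np.vstack([a, b, mid]), seed=0)
        assert labels[-1] == "unclassified"

    def test_permutation_invariance(self, features):
        labels = na.classify_units(features, seed=0)
        perm = np.random.default_rng(2).permutation(len(features))
        permuted = na.classify_units(features[perm], seed=0)
        assert [permuted[i] for i in np.argsort(perm)] == labels

    def test_leave_one_out_changes_center_by_leverage_only(self, features):
        """Removing unit i moves a cluster mean by (x_i - mean) / (n - 1)."""
        members = features[:30]
        full_mean = members.mean(axis=0)
        for i in (0, 7, 29):
            loo = np.delete(members, i, axis=0).mean(axis=0)
            expected_shift = (full_mean - members[i]) / (len(members) - 1)
            np.testing.assert_allclose(loo - full_mean, expected_shift,
                                       atol=1e-12)


class TestRewardResponsiveness:
    def test_strong_responder_detected(self):
        unit = make_unit(n_trials=60, base_spikes=1,
                         delivery_extra=[3] * 30)
        responsive, p = na.reward_responsiveness(unit)
        assert responsive and p < 1e-6

    def test_zero_spike_unit_not_responsive(self):
        unit = make_unit(n_trials=20, base_spikes=0)
        responsive, p = na.reward_responsiveness(unit)
        assert not responsive and p == 1.0

    def test_requires_ten_rewarded_trials(self):
        unit = make_unit(n_trials=10)  # only 5 rewarded
        with pytest.raises(WindowingError):
            na.reward_responsiveness(unit)

    def test_baseline_variant_runs(self):
        unit = make_unit(n_trials=60, base_spikes=1, delivery_extra=[3] * 30)
        responsive, _ = na.reward_responsiveness(unit, baseline="pre_reward")
        assert responsive


class TestDifferenceScores:
    def test_constant_rate_unit_scores_zero(self):
        unit = make_unit(n_trials=40)
        scores = na.difference_scores(unit)
        assert scores["delivery_score"] == pytest.approx(0.0)
        assert scores["omission_score"] == pytest.approx(0.0)
        assert scores["cue_score"] == pytest.approx(0.0)

    def test_sign_conventions(self):
        """Early extra delivery spikes -> positive delivery score; early
        missing omission spikes -> negative omission score; late-growing cue
        contrast -> positive cue score."""
        n_occ = 10
        unit = make_unit(n_trials=40, base_spikes=4,
                         delivery_extra=[4] * 3 + [0] * (n_occ - 3),
                         omission_missing=[4] * 3 + [0] * (n_occ - 3),
                         cue_extra=[0] * (n_occ - 3) + [4] * 3)
        scores = na.difference_scores(unit)
        assert scores["delivery_score"] > 0
        assert scores["omission_score"] < 0
        assert scores["cue_score"] > 0

    def test_shift_invariance(self):
        """Adding a constant rate to every trial leaves the delivery and
        omission scores unchanged."""
        kw = dict(n_trials=40, delivery_extra=[2] * 4 + [0] * 6,
                  omission_missing=[1] * 4 + [0] * 6)
        a = na.difference_scores(make_unit(base_spikes=2, **kw))
        b = na.difference_scores(make_unit(base_spikes=6, **kw))
        assert a["delivery_score"] == pytest.approx(b["delivery_score"])
        assert a["omission_score"] == pytest.approx(b["omission_score"])

    def test_windowing_error(self):
        unit = make_unit(n_trials=8)
        with pytest.raises(WindowingError):
            na.difference_scores(unit, early_n=5, late_n=5)


class TestPopulationTests:
    def test_signed_rank_symmetry(self):
        x = np.array([0.3, -0.8, 1.2, 0.5, -0.2, 0.9, 1.5])
        ta = pd.DataFrame({"delivery_score": x, "omission_score": x,
                           "cue_score": x})
        tb = pd.DataFrame({"delivery_score": -x, "omission_score": -x,
                           "cue_score": -x})
        ra, rb = na.population_tests(ta), na.population_tests(tb)
        assert ra["delivery_score"]["signed_rank_p"] == \
            pytest.approx(rb["delivery_score"]["signed_rank_p"])

    def test_identical_tables_rank_sum_p_one(self):
        x = np.linspace(-1, 1, 12)
        t = pd.DataFrame({"delivery_score": x, "omission_score": x,
                          "cue_score": x})
        r = na.population_tests(t, t.copy())
        assert r["delivery_score"]["rank_sum_p"] == pytest.approx(1.0)

    def test_all_zero_scores_degenerate(self):
        t = pd.DataFrame({"delivery_score": np.zeros(10),
                          "omission_score": np.zeros(10),
                          "cue_score": np.zeros(10)})
        r = na.population_tests(t)
        assert r["delivery_score"]["signed_rank_p"] == 1.0

    def test_minimum_group_size(self):
        t = pd.DataFrame({"delivery_score": [1.0] * 5,
                          "omission_score": [1.0] * 5,
                          "cue_score": [1.0] * 5})
        with pytest.raises(SchemaError):
            na.population_tests(t)


def test_csv_round_trip(tmp_path):
    units = [make_unit(f"u{i}", n_trials=12, delivery_extra=[i] * 3)
             for i in range(3)]
    prefix = str(tmp_path / "pop_")
    na.save_units(units, prefix)
    back = na.load_units(prefix)
    assert [u.unit_id for u in back] == [u.unit_id for u in units]
    for u0, u1 in zip(units, back):
        assert len(u0.spikes) == len(u1.spikes)
        for a, b in zip(u0.spikes, u1.spikes):
            np.testing.assert_allclose(np.sort(a), b, atol=1e-12)
        assert u0.waveform_features == pytest.approx(u1.waveform_features)
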