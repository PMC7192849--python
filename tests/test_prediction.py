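from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stressmark.io_core import FollowupRecord, HospitalizationRecord
from stressmark.prediction import (
    MarkerSeries,
    all_future_outcome,
    combine_features,
    cox_hr,
    enumerate_strata,
    first_year_outcome,
    hosp_frequency,
    longitudinal_features,
    panel_score,
    roc_auc,
    slope,
    state_labels,
    stratified_evaluation,
    zscore_by_stratum,
)
from stressmark.prediction import testing_points as best_stratum_points

from conftest import cox_beta_oracle, make_visit, roc_auc_oracle


class TestZscore:
    def test_single_cell(self):
        z = zscore_by_stratum(
            pd.Series([10.0, 20.0, 30.0]),
            pd.Series(["M"] * 3), pd.Series(["BP"] * 3),
        )
        np.testing.assert_allclose(z, [-1, 0, 1])

    def test_singleton_cell_zero(self):
        z = zscore_by_stratum(
            pd.Series([10.0]), pd.Series(["M"]), pd.Series(["BP"])
        )
        assert z.iloc[0] == 0.0

    def test_cells_independent(self):
        levels = pd.Series([1.0, 2.0, 3.0, 100.0, 200.0, 300.0])
        gender = pd.Series(["M"] * 3 + ["F"] * 3)
        dx = pd.Series(["BP"] * 6)
        z = zscore_by_stratum(levels, gender, dx)
        np.testing.assert_allclose(z[:3], [-1, 0, 1])
        np.testing.assert_allclose(z[3:], [-1, 0, 1])


class TestSlope:
    def test_ratio_over_days(self):
        assert slope(2.0, 1.0, 100) == pytest.approx(0.02)
        assert slope(1.0, 1.0, 50) == pytest.approx(0.02)

    def test_near_zero_previous_guarded_and_capped(self):
        assert slope(1.0, 0.0, 10, eps=0.01, cap=10.0) == 10.0
        assert slope(-1.0, 0.0, 10, eps=0.01, cap=10.0) == -10.0

    def test_nonpositive_days_rejected(self):
        with pytest.raises(ValueError):
            slope(1.0, 1.0, 0)


class TestLongitudinalFeatures:
    def _series(self, levels, direction="increased"):
        dates = [date(2016, 1, 1) + timedelta(days=100 * i)
                 for i in range(len(levels))]
        return MarkerSeries("s", dates, levels, direction)

    def test_single_visit_excluded(self):
        with pytest.raises(ValueError):
            longitudinal_features(self._series([1.0]))

    def test_extremes_max_for_increased_min_for_decreased(self):
        feats = longitudinal_features(self._series([0.5, 2.0, 1.0]))
        assert feats.level == 1.0
        assert feats.extreme_level == 2.0
        feats_d = longitudinal_features(
            self._series([0.5, 2.0, 1.0], "decreased")
        )
        assert feats_d.extreme_level == 0.5

    def test_rising_series_beats_flat(self):
        rising = longitudinal_features(self._series([0.0, 0.5, 1.0]))
        flat = longitudinal_features(self._series([1.0, 1.0, 1.0]))
        sum_rising = (rising.level + rising.slope + rising.extreme_level
                      + rising.extreme_slope)
        sum_flat = (flat.level + flat.slope + flat.extreme_level
                    + flat.extreme_slope)
        assert sum_rising >= sum_flat

    def test_identical_subjects_combine_to_zero(self):
        feats = pd.DataFrame(
            {"level": [1.0] * 4, "slope": [0.1] * 4,
             "extreme_level": [2.0] * 4, "extreme_slope": [0.2] * 4}
        )
        assert (combine_features(feats) == 0).all()


class TestPanel:
    def test_single_increased(self):
        assert panel_score({"m": 1.2}, {"m": "increased"}) == 1.2

    def test_decreased_subtracted(self):
        score = panel_score(
            {"a": 1.0, "b": -0.5}, {"a": "increased", "b": "decreased"}
        )
        assert score == pytest.approx(1.5)

    def test_empty_panel_zero(self):
        assert panel_score({}, {}) == 0.0

    def test_additive_over_disjoint_panels(self):
        directions = {"a": "increased", "b": "decreased", "c": "increased"}
        z = {"a": 0.3, "b": -1.1, "c": 2.0}
        whole = panel_score(z, directions)
        parts = panel_score({"a": z["a"]}, directions) + panel_score(
            {"b": z["b"], "c": z["c"]}, directions
        )
        assert whole == pytest.approx(parts)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([3, 4, 1, 2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_half(self):
        auc, p = roc_auc([1, 1], [1, 0])
        assert auc == 0.5

    def test_mixed_ties_example(self):
        """pos=[2,3], neg=[1,3]: wins 2 (3>1, 2>1), tie 1 -> 2.5/4."""
        auc, _ = roc_auc([2, 3, 1, 3], [1, 1, 0, 0])
        assert auc == pytest.approx(0.625)

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=15),
        st.lists(st.integers(0, 5), min_size=1, max_size=15),
    )
    @settings(max_examples=200, deadline=None)
    def test_equals_pair_enumeration_oracle(self, pos, neg):
        scores = np.array(pos + neg, dtype=float)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_oracle(scores, labels))

    @given(
        st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=2, max_size=12
        ),
        st.integers(1, 11),
    )
    @settings(max_examples=100, deadline=None)
    def test_complement_symmetry(self, scores, n_pos):
        n_pos = min(n_pos, len(scores) - 1)
        labels = [1] * n_pos + [0] * (len(scores) - n_pos)
        auc, _ = roc_auc(scores, labels)
        auc_neg, _ = roc_auc([-s for s in scores], labels)
        assert auc + auc_neg == pytest.approx(1.0)

    def test_one_class_empty_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestLabelsAndOutcomes:
    @pytest.mark.parametrize("life,label", [(67, 1), (66, 0), (100, 1)])
    def test_state_threshold_inclusive(self, life, label):
        v = make_visit(life=life, health=life)
        assert state_labels([v]) == [label]

    def _visit(self):
        return make_visit(subject_id="s", visit_date=date(2016, 1, 1),
                          sample_id="x")

    def test_first_year_event(self):
        hosp = [HospitalizationRecord("s", date(2016, 4, 10), True)]
        assert first_year_outcome(self._visit(), hosp) == (100, 1)

    def test_first_year_censored_at_365(self):
        assert first_year_outcome(self._visit(), []) == (365, 0)
        late = [HospitalizationRecord("s", date(2017, 2, 5), True)]
        assert first_year_outcome(self._visit(), late) == (365, 0)

    def test_non_stress_admissions_ignored(self):
        hosp = [HospitalizationRecord("s", date(2016, 4, 10), False)]
        assert first_year_outcome(self._visit(), hosp) == (365, 0)

    def test_all_future_event_beyond_year(self):
        hosp = [HospitalizationRecord(
            "s", date(2016, 1, 1) + timedelta(days=900), True)]
        fup = [FollowupRecord("s", date(2021, 1, 1))]
        assert all_future_outcome(self._visit(), hosp, fup) == (900, 1)

    def test_all_future_censored_at_last_note(self):
        fup = [FollowupRecord("s", date(2016, 1, 1) + timedelta(days=2000))]
        assert all_future_outcome(self._visit(), [], fup) == (2000, 0)

    def test_zero_followup_flagged(self):
        fup = [FollowupRecord("s", date(2016, 1, 1))]
        assert all_future_outcome(self._visit(), [], fup) == (0, 0)

    def test_hosp_frequency(self):
        hosp = [
            HospitalizationRecord("s", date(2016, 6, 1), True),
            HospitalizationRecord("s", date(2017, 1, 1), True),
        ]
        fup = [FollowupRecord("s", date(2016, 1, 1) + timedelta(days=730))]
        freq = hosp_frequency(self._visit(), hosp, fup)
        assert freq == pytest.approx(2 / 730)


class TestCox:
    def _instance(self, seed=0, n=60, beta=0.8):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        times = rng.exponential(1.0 / (0.01 * np.exp(beta * x)))
        events = (times < 200).astype(int)
        times = np.minimum(times, 200) + rng.uniform(0, 1e-6, n)  # untie
        return times, events, x

    def test_matches_grid_search_oracle_small_instances(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 5
            x = rng.normal(size=n)
            times = np.sort(rng.uniform(1, 100, size=n))
            events = np.array([1, 1, 1, 0, 0])
            rng.shuffle(events)
            if events.sum() < 2:
                events[:2] = 1
            beta_oracle = cox_beta_oracle(times, events, x)
            if abs(beta_oracle) > 4:  # near-separated instance
                continue
            hr, _ = cox_hr(times, events, x, "increased")
            assert abs(np.log(hr) - beta_oracle) < 1e-3, seed

    def test_orientation_flip_under_negation(self):
        times, events, x = self._instance(1)
        hr, _ = cox_hr(times, events, x, "increased")
        hr_neg, _ = cox_hr(times, events, -x, "increased")
        assert hr_neg == pytest.approx(1.0 / hr, rel=1e-6)

    def test_decreased_direction_inverts_ratio(self):
        times, events, x = self._instance(2)
        hr_inc, p_inc = cox_hr(times, events, x, "increased")
        hr_dec, p_dec = cox_hr(times, events, x, "decreased")
        assert hr_dec == pytest.approx(1.0 / hr_inc, rel=1e-9)
        assert p_dec == pytest.approx(p_inc)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_hr([1.0, 2.0], [0, 0], [0.1, 0.2])


class TestStratifiedEvaluation:
    def _cohort(self):
        rng = np.random.default_rng(5)
        visits, rows = [], []
        k = 0
        for g in ("M", "F"):
            for dx in ("BP", "SZ"):
                for s in range(4):
                    sid = f"{g}{dx}{s}"
                    for j, life in enumerate((20, 80)):
                        sample = f"samp{k}"
                        k += 1
                        visits.append(
                            make_visit(
                                subject_id=sid,
                                visit_date=date(2016, 1 + j, 1),
                                gender=g, diagnosis=dx,
                                life=life, health=life, sample_id=sample,
                            )
                        )
                        # marker tracks stress + noise
                        rows.append(
                            (sample, 6.0 + 0.8 * (life >= 67)
                             + rng.normal(0, 0.3))
                        )
        levels = pd.DataFrame(
            {"m1": dict(rows)}
        ).T
        return visits, levels

    def test_strata_enumeration_includes_psychosis_pool(self):
        visits, _ = self._cohort()
        names = [name for name, _, _ in enumerate_strata(visits)]
        assert "all" in names
        assert {"M", "F"} <= set(names)
        assert "M-BP" in names and "F-SZ" in names
        assert "M-PSYCHOSIS" in names

    def test_state_evaluation_finds_tracking_marker(self):
        visits, levels = self._cohort()
        markers = pd.DataFrame(
            {"direction": ["increased"]}, index=["m1"]
        )
        results = stratified_evaluation(
            markers, visits, levels,
            outcomes=("state_high_stress",), modes=("cross_sectional",),
        )
        best = results[results["stratum"] == "all"].iloc[0]
        assert best["auc"] > 0.8
        assert best["auc_p"] < 0.05
        assert best["n_total"] == 32
        assert best_stratum_points(results, "state_high_stress") == 8

    def test_testing_points_hierarchy(self):
        rows = [
            ("m", "M-BP", "gender_dx", "cross_sectional",
             "state_high_stress", 2, 10, 0.9, 0.01, 0.1, 0.1, 0.3,
             np.nan, np.nan),
            ("m", "M", "gender", "cross_sectional", "state_high_stress",
             4, 20, 0.8, 0.02, 0.1, 0.1, 0.3, np.nan, np.nan),
        ]
        results = pd.DataFrame(
            rows,
            columns=[
                "probeset_id", "stratum", "stratum_level", "mode",
                "outcome", "n_positive", "n_total", "auc", "auc_p", "t_p",
                "pearson_r", "pearson_p", "hazard_ratio", "hr_p",
            ],
        )
        assert best_stratum_points(results, "state_high_stress") == 6
        results.loc[1, "auc_p"] = 0.5
        assert best_stratum_points(results, "state_high_stress") == 4
        assert best_stratum_points(results, "hosp_all_future") == 0
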