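"""Mouse PDX trajectory classification, survival analysis, engraftment."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xenocall.calls import ResponseCall
from xenocall.mouse import (
    SurvivalRecord,
    TumorVolumeSeries,
    classify_mouse_trajectory,
    engraftment_status,
    event_time_quadrupling,
    group_objective_response,
    km_estimate,
    logrank_test,
)


def three_point(v0, v1, v2, treatment_end=28.0, study_end=28.0):
    return TumorVolumeSeries(
        "m1",
        "model",
        "arm",
        ((0.0, v0), (14.0, v1), (28.0, v2)),
        treatment_start_day=0.0,
        treatment_end_day=treatment_end,
        study_end_day=study_end,
    )


def rule_oracle(v0, v1, v2, cutoff=100.0):
    """Independent rule-by-rule reading of the trajectory criteria for a
    3-point course measured at days 0/14/28 with treatment over [0, 28]:
    the day-28 measurement is the only one in the post-cessation window."""
    vols = [v0, v1, v2]
    if v2 < cutoff:
        return "MCR"
    if min(vols) < cutoff:
        return "CR"
    if (v0 - min(vols)) / v0 * 100 >= 50:
        return "PR"
    return "SD" if v2 <= 1.25 * v0 else "PD"


class TestTrajectoryClassifier:
    @pytest.mark.parametrize(
        "vols, window, expected",
        [
            ((300, 120, 200), (14, 28), "PR"),  # 60% regression, measurable nadir
            ((150, 60, 400), (14, 28), "CR"),  # below 100 mm^3 once
            ((150, 120, 180), (14, 28), "SD"),  # 20% regression, +20% at end
            ((150, 120, 190), (14, 28), "PD"),  # +26.7% at end
        ],
    )
    def test_archetypal_trajectories(self, vols, window, expected):
        series = three_point(*vols, treatment_end=window[0], study_end=window[1])
        assert classify_mouse_trajectory(series).category == expected

    def test_mcr_holds_three_weeks_past_cessation(self):
        series = TumorVolumeSeries(
            "m1",
            "model",
            "arm",
            ((0.0, 150.0), (28.0, 40.0), (35.0, 55.0), (49.0, 70.0)),
            treatment_start_day=0.0,
            treatment_end_day=28.0,
            study_end_day=49.0,
        )
        assert classify_mouse_trajectory(series).category == "MCR"

    def test_regrowth_inside_window_demotes_mcr_to_cr(self):
        series = TumorVolumeSeries(
            "m1",
            "model",
            "arm",
            ((0.0, 150.0), (28.0, 40.0), (35.0, 130.0), (49.0, 260.0)),
            treatment_start_day=0.0,
            treatment_end_day=28.0,
            study_end_day=49.0,
        )
        assert classify_mouse_trajectory(series).category == "CR"

    def test_oracle_grid_agreement(self):
        """Exhaustive 3-point grid against the independent rule oracle."""
        grid_v0 = [120.0, 150.0, 300.0]
        for v0 in grid_v0:
            steps = np.linspace(10.0, 2.5 * v0, 25)
            boundary = [99.9, 100.0, 100.1, 0.5 * v0, 1.25 * v0]
            values = sorted(set(steps) | set(boundary))
            for v1 in values:
                for v2 in values:
                    got = classify_mouse_trajectory(three_point(v0, v1, v2))
                    assert got.category == rule_oracle(v0, v1, v2), (v0, v1, v2)

    @given(
        v0=st.floats(min_value=250, max_value=400),
        v1=st.floats(min_value=210, max_value=600),
        v2=st.floats(min_value=210, max_value=800),
        scale=st.floats(min_value=1.0, max_value=50.0),
    )
    def test_scale_invariance_away_from_cutoff(self, v0, v1, v2, scale):
        """Categories depend only on relative change once trajectories are
        bounded above the measurable cutoff (scaling up cannot cross it)."""
        base = classify_mouse_trajectory(three_point(v0, v1, v2)).category
        scaled = classify_mouse_trajectory(
            three_point(v0 * scale, v1 * scale, v2 * scale)
        ).category
        assert base == scaled

    def test_requires_pretreatment_measurement(self):
        with pytest.raises(ValueError, match="at or before treatment start"):
            TumorVolumeSeries(
                "m",
                "model",
                "arm",
                ((5.0, 100.0),),
                treatment_start_day=0.0,
                treatment_end_day=10.0,
                study_end_day=10.0,
            )


class TestGroupResponse:
    @pytest.mark.parametrize(
        "cats, expected",
        [
            (["PR", "PR", "CR"], "PR"),
            (["PD", "PD", "SD", "CR"], "PD"),  # even split resolves worse
            (["CR"], "CR"),
            (["SD", "PR"], "SD"),
            (["MCR", "MCR", "CR", "PR", "PD"], "CR"),
        ],
    )
    def test_median_with_worse_tie(self, cats, expected):
        calls = [ResponseCall("mouse", c) for c in cats]
        assert group_objective_response(calls).category == expected

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_objective_response([])


class TestEventFreeSurvival:
    def test_exact_quadrupling_hit(self):
        s = three_point(100, 200, 400)
        assert event_time_quadrupling(s) == SurvivalRecord("m1", 28.0, True)

    def test_log_linear_interpolated_crossing(self):
        s = TumorVolumeSeries(
            "m1", "model", "arm", ((0, 100.0), (7, 300.0), (14, 600.0)),
            treatment_start_day=0, treatment_end_day=14, study_end_day=14,
        )
        rec = event_time_quadrupling(s)
        expected = 7 + 7 * (math.log(400) - math.log(300)) / (
            math.log(600) - math.log(300)
        )
        assert rec.event
        assert rec.time_days == pytest.approx(expected)
        # brute-force fine-grid crossing search on the latent exponential
        grid = np.linspace(7, 14, 2_000_001)
        latent = 300.0 * (600.0 / 300.0) ** ((grid - 7) / 7)
        brute = grid[np.argmax(latent >= 400.0)]
        assert rec.time_days == pytest.approx(brute, abs=1e-4)

    def test_censored_when_never_quadrupled(self):
        s = TumorVolumeSeries(
            "m1", "model", "arm", ((0, 100.0), (15, 200.0), (30, 350.0)),
            treatment_start_day=0, treatment_end_day=15, study_end_day=30,
        )
        assert event_time_quadrupling(s) == SurvivalRecord("m1", 30.0, False)


class TestKaplanMeier:
    def test_closed_form_two_events(self):
        S = km_estimate([SurvivalRecord("a", 5, True), SurvivalRecord("b", 10, True)])
        assert S(4.9) == 1.0
        assert S(5.0) == 0.5
        assert S(9.9) == 0.5
        assert S(10.0) == 0.0

    def test_all_censored_is_flat(self):
        S = km_estimate([SurvivalRecord(str(i), t, False) for i, t in enumerate([3, 9])])
        assert S(100.0) == 1.0

    def test_product_limit_with_censoring(self):
        S = km_estimate([SurvivalRecord("a", 5, True), SurvivalRecord("b", 8, False)])
        assert S(5.0) == 0.5
        assert S(20.0) == 0.5

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(10, 40)
        records = [SurvivalRecord(str(i), t, True) for i, t in enumerate(times)]
        S = km_estimate(records)
        for t in (1.0, 5.0, 12.0):
            assert S(t) == pytest.approx(np.mean(times > t))

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([SurvivalRecord("a", 0.0, True)])


class TestLogrank:
    def test_identical_groups_null(self):
        g = [SurvivalRecord(str(i), t, True) for i, t in enumerate([1, 2, 3])]
        stat, p = logrank_test(g, g)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        ga = [SurvivalRecord(str(i), t, True) for i, t in enumerate([1, 2, 3])]
        gb = [SurvivalRecord(str(i), t, True) for i, t in enumerate([10, 11, 12])]
        stat, p = logrank_test(ga, gb)
        assert p < 0.05

    def test_no_events_degenerate(self):
        g = [SurvivalRecord("a", 5.0, False)]
        with pytest.warns(UserWarning, match="no events"):
            stat, p = logrank_test(g, g)
        assert (stat, p) == (0.0, 1.0)

    def test_matches_hand_computed_statistic(self):
        """Hand-computed hypergeometric O-E/V on a small tied dataset."""
        ga = [SurvivalRecord(str(i), t, True) for i, t in enumerate([2.0, 4.0, 4.0])]
        gb = [SurvivalRecord(str(i), t, True) for i, t in enumerate([4.0, 6.0])]
        # risk sets: t=2 (3,2): O=1 E=0.6 V=0.24
        # t=4, d=3 of n=4 (2,2): O=2 E=1.5 V=0.25
        # t=6, only one subject left: E and V contribute 0
        stat, _ = logrank_test(ga, gb)
        expected = (3 - 0.6 - 1.5) ** 2 / (0.24 + 0.25)
        assert stat == pytest.approx(expected)


class TestEngraftment:
    def test_reached_threshold(self):
        s = TumorVolumeSeries(
            "m1", "model", "arm", ((0, 10.0), (35, 800.0), (49, 1000.0)),
            treatment_start_day=0, treatment_end_day=49, study_end_day=49,
        )
        assert engraftment_status(s) == ("engrafted", 49.0)

    def test_interpolated_crossing(self):
        s = TumorVolumeSeries(
            "m1", "model", "arm", ((0, 10.0), (35, 800.0), (42, 1250.0)),
            treatment_start_day=0, treatment_end_day=42, study_end_day=42,
        )
        status, t = engraftment_status(s)
        assert status == "engrafted"
        expected = 35 + 7 * (math.log(1000) - math.log(800)) / (
            math.log(1250) - math.log(800)
        )
        assert t == pytest.approx(expected)
        assert t == pytest.approx(38.5, abs=0.05)

    def test_failure_at_holding_time(self):
        s = TumorVolumeSeries(
            "m1", "model", "arm", tuple((d, 0.0) for d in range(0, 366, 30)),
            treatment_start_day=0, treatment_end_day=365, study_end_day=365,
        )
        assert engraftment_status(s) == ("failed", None)
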