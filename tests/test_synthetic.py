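"""Synthetic-data generators: determinism, validity, ground-truth recovery."""

from dataclasses import replace

import numpy as np
import pytest

from xenocall.calls import ResponseCall
from xenocall.mouse import classify_mouse_trajectory, group_objective_response
from xenocall.synthetic import (
    MOUSE_ARCHETYPES,
    FishScenario,
    HtsScenario,
    MouseScenario,
    gen_fish_experiment,
    gen_hts_plate,
    gen_mouse_cohort,
    gen_patient_course,
    mouse_archetype_scenario,
)
from xenocall.zebrafish import baseline_band, classify_fish_group


class TestMouseGenerator:
    def test_noiseless_exponential_growth(self):
        scenario = MouseScenario(
            "PD",
            n_mice=1,
            start_volume_mm3=150.0,
            kill_rate_per_day=0.0,
            noise_cv=0.0,
            schedule_days=tuple(np.arange(0.0, 28.1, 3.5)),
            treatment_end_day=28.0,
        )
        series = gen_mouse_cohort(scenario, seed=0)[0]
        assert series.volumes[-1] == pytest.approx(150 * 2**4)

    def test_cr_preset_crosses_measurable_cutoff(self):
        scenario = replace(mouse_archetype_scenario("CR"), noise_cv=0.0, n_mice=1)
        series = gen_mouse_cohort(scenario, seed=0)[0]
        assert min(series.volumes) < 100.0

    def test_pr_preset_classifies_pr_under_noise(self):
        scenario = replace(mouse_archetype_scenario("PR"), noise_cv=0.1, n_mice=6)
        calls = [
            classify_mouse_trajectory(s).category
            for s in gen_mouse_cohort(scenario, seed=1)
        ]
        assert sum(c == "PR" for c in calls) >= 5

    @pytest.mark.parametrize("archetype", MOUSE_ARCHETYPES)
    def test_zero_noise_archetype_recovery(self, archetype):
        scenario = replace(mouse_archetype_scenario(archetype), noise_cv=0.0)
        for series in gen_mouse_cohort(scenario, seed=0):
            assert classify_mouse_trajectory(series).category == archetype

    def test_deterministic_and_positive(self):
        scenario = mouse_archetype_scenario("SD", noise_cv=0.2)
        a = gen_mouse_cohort(scenario, seed=5)
        b = gen_mouse_cohort(scenario, seed=5)
        assert a == b
        assert all(v > 0 for s in a for v in s.volumes)
        c = gen_mouse_cohort(scenario, seed=6)
        assert a != c

    def test_invalid_scenario_names_field(self):
        with pytest.raises(ValueError, match="n_mice"):
            MouseScenario("PD", n_mice=0)
        with pytest.raises(ValueError, match="noise_cv"):
            MouseScenario("PD", noise_cv=-0.1)


class TestFishGenerator:
    def test_group_structure(self):
        scenario = FishScenario(treatment_effects={"a": 0.5, "b": 1.0})
        groups = gen_fish_experiment(scenario, seed=0)
        labels = {(g.arm, g.day) for g in groups}
        assert labels == {("control", "1dpi"), ("control", "4dpi"), ("a", "4dpi"), ("b", "4dpi")}

    def test_counts_are_nonnegative_integers(self):
        scenario = FishScenario(treatment_effects={"a": 0.3}, dispersion=2.0)
        for g in gen_fish_experiment(scenario, seed=3):
            assert all(isinstance(c, int) and c >= 0 for c in g.counts)

    def test_deterministic_counts_hit_stated_means(self):
        scenario = FishScenario(
            treatment_effects={"a": 1.0}, dispersion=0.0, control_growth_factor=1.0
        )
        groups = {g.arm: g for g in gen_fish_experiment(scenario, seed=0) if g.day == "4dpi"}
        one_dpi = [g for g in gen_fish_experiment(scenario, seed=0) if g.day == "1dpi"][0]
        assert groups["a"].mean == one_dpi.mean == 150.0

    def test_growth_factor_doubles_control(self):
        scenario = FishScenario(treatment_effects={}, dispersion=0.0, control_growth_factor=2.0)
        groups = gen_fish_experiment(scenario, seed=0)
        assert [g.mean for g in groups] == [150.0, 300.0]

    def test_adding_arm_does_not_perturb_others(self):
        small = FishScenario(treatment_effects={"a": 0.5}, dispersion=5.0)
        big = FishScenario(treatment_effects={"a": 0.5, "b": 2.0}, dispersion=5.0)
        counts_small = {g.arm: g.counts for g in gen_fish_experiment(small, seed=9)}
        counts_big = {g.arm: g.counts for g in gen_fish_experiment(big, seed=9)}
        assert counts_small["a"] == counts_big["a"]
        assert counts_small["control"] == counts_big["control"]

    def test_strong_kill_classifies_as_response(self):
        scenario = FishScenario(
            treatment_effects={"t": 0.3}, dispersion=5.0, n_larvae_per_group=16
        )
        groups = gen_fish_experiment(scenario, seed=7)
        band = baseline_band(groups[0])
        treated = [g for g in groups if g.arm == "t"][0]
        assert classify_fish_group(treated, band).category == "R"

    @pytest.mark.parametrize(
        "effect, expected", [(0.3, "R"), (0.5, "SD"), (1.0, "PD")]
    )
    def test_zero_noise_regime_recovery(self, effect, expected):
        scenario = FishScenario(treatment_effects={"t": effect}, dispersion=0.0)
        groups = gen_fish_experiment(scenario, seed=0)
        band = baseline_band(groups[0])
        treated = [g for g in groups if g.arm == "t"][0]
        assert classify_fish_group(treated, band).category == expected

    def test_group_size_bounds_enforced(self):
        with pytest.raises(ValueError, match="n_larvae_per_group"):
            FishScenario(n_larvae_per_group=8)


class TestPatientGenerator:
    def test_sums_follow_percent_changes(self):
        course = gen_patient_course("p", "t", 100.0, [-40, -40], [6, 12])
        assert [s.sum_diameters_mm for s in course.scans] == [100.0, 60.0, 60.0]

    def test_complete_disappearance(self):
        course = gen_patient_course("p", "t", 100.0, [-100], [6])
        assert course.scans[-1].sum_diameters_mm == 0.0

    def test_changes_are_relative_to_baseline(self):
        course = gen_patient_course("p", "t", 100.0, [-10, 25], [6, 12])
        assert course.scans[2].sum_diameters_mm == pytest.approx(125.0)

    def test_negative_sum_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            gen_patient_course("p", "t", 100.0, [-140], [6])


class TestHtsGenerator:
    def test_plate_geometry(self):
        plate, _ = gen_hts_plate(HtsScenario(), seed=0)
        assert len(plate.concentrations_nmol) == 5
        assert all(len(reps) == 2 for reps in plate.viability)

    def test_noiseless_midpoint(self):
        plate, _ = gen_hts_plate(
            HtsScenario(top=1.0, bottom=0.0, hill=1.0, true_ic50_nmol=50.0, replicate_sd=0.0),
            seed=0,
        )
        idx = plate.concentrations_nmol.index(50.0)
        assert plate.viability[idx] == pytest.approx((0.5, 0.5))

    def test_cohort_statistics_near_specified(self):
        _, ref = gen_hts_plate(HtsScenario(cohort_n=500), seed=1)
        assert ref.auc_mean == pytest.approx(0.8, abs=0.02)
        assert ref.logic50_sd == pytest.approx(0.5, abs=0.1)

    def test_determinism(self):
        assert gen_hts_plate(HtsScenario(), 4) == gen_hts_plate(HtsScenario(), 4)
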