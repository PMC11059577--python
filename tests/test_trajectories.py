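"""Arm trajectories: stopping rule, waning, catch-up, natural progression."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from obesim.parameters_io import CatchUpSpec, GlycemicMix
from obesim.synthetic_data import SyntheticSpec, generate_parameter_set
from obesim.trajectories import (
    apply_bariatric_effect,
    apply_catch_up,
    apply_waning,
    build_arm_trajectory,
    cycle_grid,
    natural_weight_gain,
    prediabetes_reversal,
)


class TestCycleGrid:
    def test_quarterly_then_annual(self):
        grid = cycle_grid(40)
        assert len(grid) == 43
        assert [dt for _, _, dt in grid[:4]] == [0.25] * 4
        assert all(dt == 1.0 for _, _, dt in grid[4:])
        assert grid[4] == (5, 1.0, 1.0)
        assert grid[-1][1] + grid[-1][2] == 40.0


class TestWaning:
    def test_definitional_product(self):
        assert apply_waning(-10.0, 0.9) == pytest.approx(-9.0)

    def test_held_constant_factor_unchanged(self):
        assert apply_waning(-0.2, 0.9, held_constant=True) == -0.2

    def test_ratio_one_is_identity(self):
        assert apply_waning(-6.2, 1.0) == -6.2

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            apply_waning(-10.0, -0.1)


class TestCatchUp:
    def test_ara_style_schedule_year2(self):
        spec = CatchUpSpec(cumulative_fractions=(0.33, 0.67, 1.0))
        # gap of 10 units: 6.7 closed by end of year 2
        assert apply_catch_up(0.0, 10.0, spec, 2.0) == pytest.approx(6.7)

    def test_zero_years_unchanged(self):
        spec = CatchUpSpec(cumulative_fractions=(1.0,))
        assert apply_catch_up(3.0, 10.0, spec, 0.0) == 3.0

    def test_completion_returns_reference_exactly(self):
        spec = CatchUpSpec(cumulative_fractions=(1.0,))
        assert apply_catch_up(-12.3, 0.0, spec, 1.0) == 0.0
        assert apply_catch_up(-12.3, 0.0, spec, 7.0) == 0.0

    @given(st.floats(-20, 20), st.floats(-20, 20),
           st.floats(0, 10))
    @settings(max_examples=100, deadline=None)
    def test_monotone_gap_closure(self, current, reference, years):
        spec = CatchUpSpec(cumulative_fractions=(0.33, 0.67, 1.0))
        now = apply_catch_up(current, reference, spec, years)
        later = apply_catch_up(current, reference, spec, years + 1.0)
        assert abs(later - reference) <= abs(now - reference) + 1e-12


class TestNaturalWeightGain:
    def test_all_male_cohort(self, step1_params):
        profile = step1_params.cohort.model_copy(
            update={"proportion_male": 1.0})
        gain = natural_weight_gain(profile, 50.0,
                                   step1_params.natural_progression)
        assert gain == pytest.approx(0.402)

    def test_zero_after_maximum_age(self, step1_params):
        assert natural_weight_gain(step1_params.cohort, 70.0,
                                   step1_params.natural_progression) == 0.0

    def test_sex_mix_reproduces_cohort_average(self, step1_params):
        # 27.4% male: 0.274*0.402 + 0.726*0.486 = 0.46298 ~ 0.463
        gain = natural_weight_gain(step1_params.cohort, 48.0,
                                   step1_params.natural_progression)
        assert gain == pytest.approx(0.463, abs=5e-4)


class TestBariatricEffect:
    def test_zero_effect_spec_is_identity(self, step1_params):
        spec = step1_params.bariatric.model_copy(update={
            "bmi_reduction_year1": 0.0, "bmi_reduction_longrun": 0.0,
            "sbp_reduction": 0.0, "tc_reduction": 0.0, "hdl_increase": 0.0})
        state = step1_params.cohort.baseline
        out = apply_bariatric_effect(state, spec, 0.5)
        assert out.bmi == state.bmi and out.sbp == state.sbp

    def test_first_year_reduction(self, step1_params):
        state = step1_params.cohort.baseline.model_copy(update={"bmi": 40.0})
        out = apply_bariatric_effect(state, step1_params.bariatric, 0.5)
        assert out.bmi == pytest.approx(40.0 * (1 - 0.23))  # 30.8

    def test_longrun_reduction(self, step1_params):
        state = step1_params.cohort.baseline.model_copy(update={"bmi": 40.0})
        out = apply_bariatric_effect(state, step1_params.bariatric, 5.0)
        assert out.bmi == pytest.approx(40.0 * (1 - 0.18))  # 32.8


class TestPrediabetesReversal:
    def test_zero_reversal_is_identity(self):
        mix = GlycemicMix(ngt=0.2, prediabetes=0.8, t2d=0.0)
        assert prediabetes_reversal(mix, 0.0, 1.0) == mix

    def test_mass_transfer_arithmetic(self):
        mix = GlycemicMix(ngt=0.2, prediabetes=0.8, t2d=0.0)
        out = prediabetes_reversal(mix, 0.5, 1.0)
        assert out.ngt == pytest.approx(0.6)
        assert out.prediabetes == pytest.approx(0.4)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_mass_conservation(self, w1, w2, reversal):
        total = w1 + w2 + 1.0
        mix = GlycemicMix(ngt=w1 / total, prediabetes=w2 / total,
                          t2d=1.0 / total)
        out = prediabetes_reversal(mix, reversal, 0.7)
        assert out.ngt + out.prediabetes + out.t2d == pytest.approx(1.0)


class TestArmTrajectory:
    def test_stopping_rule_fraction_from_cycle_3(self, treatment_trajectory):
        fractions = [c.fraction_discontinued for c in treatment_trajectory]
        assert fractions[0] == fractions[1] == 0.0
        assert all(f == pytest.approx(0.163) for f in fractions[2:])

    def test_week68_relative_bmi_changes(self, step1_params,
                                         treatment_trajectory,
                                         comparator_trajectory):
        base = step1_params.cohort.baseline.bmi
        # cycle 4 (9-12 months) carries the week-68 level in the model
        assert treatment_trajectory[3].state.bmi / base - 1 == \
            pytest.approx(-0.149, abs=1e-9)
        assert comparator_trajectory[3].state.bmi / base - 1 == \
            pytest.approx(-0.024, abs=1e-9)

    def test_null_effects_give_identical_arms(self, null_params):
        tt = build_arm_trajectory(null_params, "treatment")
        tc = build_arm_trajectory(null_params, "comparator")
        for a, b in zip(tt, tc):
            assert a.state == b.state

    def test_glycemic_mass_conserved_every_cycle(self, treatment_trajectory):
        for c in treatment_trajectory:
            m = c.state.glycemic_mix
            assert m.ngt + m.prediabetes + m.t2d == pytest.approx(1.0)

    def test_natural_progression_slope_until_age_68(self, step1_params,
                                                    comparator_trajectory):
        # after the catch-up completes (year 3) BMI rises linearly at the
        # sex-mixed slope, then flattens once the cohort reaches age 68
        h2 = step1_params.cohort.mean_height_m ** 2
        slope = 0.463 / h2
        cycles = comparator_trajectory.cycles
        post = [c for c in cycles if c.t_start >= 3.0]
        age68_t = 68.0 - step1_params.cohort.mean_age
        for a, b in zip(post, post[1:]):
            diff = b.state.bmi - a.state.bmi
            if b.t_end <= age68_t:
                assert diff == pytest.approx(slope * b.dt, rel=1e-2)
            elif a.t_start >= age68_t:
                assert diff == pytest.approx(0.0, abs=1e-12)

    def test_on_drug_fraction_tracks_duration_and_stopping(
            self, treatment_trajectory):
        on_drug = [c.fraction_on_drug for c in treatment_trajectory]
        assert on_drug[0] == on_drug[1] == 1.0
        assert on_drug[2] == on_drug[3] == on_drug[4] == pytest.approx(0.837)
        assert all(v == 0.0 for v in on_drug[5:])

    def test_bmi_floor_respected(self, step1_params):
        params = step1_params.model_copy(deep=True)
        data = params.model_dump(mode="json")
        data["cohort"]["baseline"]["bmi"] = 19.0
        data["bariatric"]["bmi_eligibility_threshold"] = 30.1
        from obesim.parameters_io import parameter_set_from_dict
        params = parameter_set_from_dict(data)
        path = build_arm_trajectory(params, "treatment")
        assert all(c.state.bmi >= 18.5 for c in path)
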