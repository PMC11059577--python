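"""Cohort engine: conservation, absorption, mortality and event logic."""

import math

import numpy as np
import pytest

from obesim.markov_engine import (
    ALIVE,
    DEAD,
    N_STATES,
    apply_acute_event,
    background_mortality,
    bariatric_uptake,
    event_rate_per_100py,
    propagate,
    run_arm,
)
from obesim.parameters_io import parameter_set_from_dict, parameter_set_to_dict
from obesim.trajectories import build_arm_trajectory


def zeroed_dynamics_params(step1_params):
    """Variant with no mortality and no events: cohort must stand still."""
    data = parameter_set_to_dict(step1_params)
    lt = data["mortality"]["life_table"]
    lt["q_male"] = [0.0] * len(lt["q_male"])
    lt["q_female"] = [0.0] * len(lt["q_female"])
    data["mortality"]["disease_specific_fraction"] = 0.0
    data["mortality"]["bmi_hazard_ratio_per_unit"] = 1.0
    eqs = data["risk_equations"]
    eqs["cv_first"]["baseline_survival"] = 1.0
    eqs["cv_recurrent"]["intercept"] = -60.0
    eqs["t2d"]["baseline_survival"] = 1.0
    eqs["knee_replacement"]["baseline_rate_table"] = None
    eqs["knee_replacement"]["baseline_rate"] = 0.0
    for c in eqs["cancers"].values():
        tab = c["baseline_incidence"]
        tab["rate_male"] = [0.0] * len(tab["rate_male"])
        tab["rate_female"] = [0.0] * len(tab["rate_female"])
    data["bariatric"]["annual_incidence_post_treatment"] = 0.0
    return parameter_set_from_dict(data)


class TestBackgroundMortality:
    def test_unit_hazard_ratio_is_bmi_independent(self, step1_params):
        model = step1_params.mortality.model_copy(
            update={"bmi_hazard_ratio_per_unit": 1.0})
        q1 = background_mortality(model, 60.0, True, 30.0)
        q2 = background_mortality(model, 60.0, True, 45.0)
        assert q1 == q2

    def test_no_deduction_and_unit_hr_recovers_all_cause(self, step1_params):
        model = step1_params.mortality.model_copy(
            update={"bmi_hazard_ratio_per_unit": 1.0,
                    "disease_specific_fraction": 0.0})
        q = background_mortality(model, 60.0, False,
                                 model.bmi_reference)
        assert q == pytest.approx(model.life_table.annual_q(60.0, False))

    def test_rate_scale_bmi_multiplier(self, step1_params):
        # HR 1.05/unit, 10 units above reference: rate multiplier 1.6289
        model = step1_params.mortality.model_copy(
            update={"bmi_hazard_ratio_per_unit": 1.05,
                    "disease_specific_fraction": 0.0})
        age = 60.0
        q_ref = background_mortality(model, age, True, model.bmi_reference)
        q_hi = background_mortality(model, age, True,
                                    model.bmi_reference + 10.0)
        ratio = math.log1p(-q_hi) / math.log1p(-q_ref)
        assert ratio == pytest.approx(1.05 ** 10, rel=1e-9)


class TestAcuteEventArithmetic:
    def test_full_case_fatality_sends_all_to_dead(self):
        events, fatal, surv = apply_acute_event(0.4, 0.1, 1.0)
        assert fatal == pytest.approx(events)
        assert surv == 0.0

    def test_zero_probability_is_identity(self):
        assert apply_acute_event(0.5, 0.0, 0.2) == (0.0, 0.0, 0.0)

    def test_product_arithmetic(self):
        # 0.5 occupancy x 0.1 event probability = 0.05 events, of which
        # case fatality 0.2 sends 0.01 to dead and 0.04 to the destination
        events, fatal, surv = apply_acute_event(0.5, 0.1, 0.2)
        assert events == pytest.approx(0.05)
        assert fatal == pytest.approx(0.01)
        assert surv == pytest.approx(0.04)


class TestBariatricUptake:
    def test_gate_below_threshold(self, step1_params):
        assert bariatric_uptake(step1_params.bariatric, 33.0, True, 1.0) == 0

    def test_zero_while_on_treatment(self, step1_params):
        assert bariatric_uptake(step1_params.bariatric, 40.0, False, 1.0) == 0

    def test_annual_passthrough_when_eligible(self, step1_params):
        p = bariatric_uptake(step1_params.bariatric, 40.0, True, 1.0)
        assert p == pytest.approx(0.004)


class TestCohortDynamics:
    def test_occupancy_conserved_every_cycle(self, treatment_trace,
                                             comparator_trace):
        for trace in (treatment_trace, comparator_trace):
            sums = trace.occupancy_end.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-10)

    def test_dead_state_absorbing(self, treatment_trace):
        dead = treatment_trace.occupancy_end[:, DEAD]
        assert np.all(np.diff(dead) >= -1e-12)

    def test_null_dynamics_cohort_stands_still(self, step1_params):
        params = zeroed_dynamics_params(step1_params)
        traj = build_arm_trajectory(params, "comparator")
        trace = run_arm(params, traj)
        assert trace.occupancy_end[:, DEAD].max() == pytest.approx(0.0)
        assert trace.life_years() == pytest.approx(
            params.settings.horizon_years, rel=1e-9)

    def test_certain_death_in_first_cycle(self, step1_params):
        data = parameter_set_to_dict(step1_params)
        lt = data["mortality"]["life_table"]
        lt["q_male"] = [1.0] * len(lt["q_male"])
        lt["q_female"] = [1.0] * len(lt["q_female"])
        data["mortality"]["disease_specific_fraction"] = 0.0
        params = parameter_set_from_dict(data)
        traj = build_arm_trajectory(params, "comparator")
        trace = run_arm(params, traj)
        # q=1 annual maps to a finite quarterly hazard, so survival of the
        # first quarter is vanishingly small rather than exactly zero
        assert trace.occupancy_end[0, DEAD] == pytest.approx(1.0, abs=1e-3)
        assert trace.occupancy_end[3, DEAD] == pytest.approx(1.0, abs=1e-9)
        assert trace.life_years() <= 0.25 + 1e-9

    def test_half_cycle_accrual_between_endpoints(self, treatment_trace):
        annual = treatment_trace.dt >= 0.5
        acc = treatment_trace.accrual[annual]
        lo = np.minimum(treatment_trace.occupancy_start[annual],
                        treatment_trace.occupancy_end[annual])
        hi = np.maximum(treatment_trace.occupancy_start[annual],
                        treatment_trace.occupancy_end[annual])
        assert np.all(acc >= lo - 1e-12) and np.all(acc <= hi + 1e-12)

    def test_lower_bmi_trajectory_never_increases_bmi_driven_events(
            self, step1_params, comparator_trace):
        data = parameter_set_to_dict(step1_params)
        data["cohort"]["baseline"]["bmi"] = 33.0  # uniformly lower path
        params = parameter_set_from_dict(data)
        traj = build_arm_trajectory(params, "comparator")
        low = run_arm(params, traj)
        for ev in ("mi", "stroke", "knee_replacement"):
            assert low.total_events(ev) <= \
                comparator_trace.total_events(ev) + 1e-12

    def test_event_rate_per_100py(self, treatment_trace):
        rate = event_rate_per_100py(treatment_trace, "knee_replacement")
        direct = 100.0 * treatment_trace.total_events("knee_replacement") \
            / treatment_trace.alive_person_years()
        assert rate == pytest.approx(direct)
        assert rate > 0.0

    def test_doubling_small_probabilities_doubles_rates(self, step1_params):
        data = parameter_set_to_dict(step1_params)
        # isolate knee replacement on an otherwise frozen cohort
        params0 = zeroed_dynamics_params(step1_params)
        d0 = parameter_set_to_dict(params0)
        d0["risk_equations"]["knee_replacement"]["baseline_rate"] = 0.001
        p1 = parameter_set_from_dict(d0)
        d0["risk_equations"]["knee_replacement"]["baseline_rate"] = 0.002
        p2 = parameter_set_from_dict(d0)
        r1 = event_rate_per_100py(
            run_arm(p1, build_arm_trajectory(p1, "comparator")),
            "knee_replacement")
        r2 = event_rate_per_100py(
            run_arm(p2, build_arm_trajectory(p2, "comparator")),
            "knee_replacement")
        assert r2 / r1 == pytest.approx(2.0, rel=0.05)


class TestPropagation:
    def test_row_sum_violation_aborts(self):
        m = np.eye(3)
        m[0, 0] = 0.9  # row sums to 0.9
        from obesim.markov_engine import TransitionConsistencyError
        with pytest.raises(TransitionConsistencyError):
            propagate([m], np.array([1.0, 0.0, 0.0]))

    def test_propagate_matches_manual_chain(self):
        m1 = np.array([[0.8, 0.15, 0.05], [0.0, 0.9, 0.1], [0, 0, 1.0]])
        m2 = np.array([[0.7, 0.2, 0.1], [0.0, 0.85, 0.15], [0, 0, 1.0]])
        occ0 = np.array([0.9, 0.1, 0.0])
        occ = propagate([m1, m2], occ0)
        assert np.allclose(occ[1], occ0 @ m1)
        assert np.allclose(occ[2], occ0 @ m1 @ m2)
        assert np.allclose(occ.sum(axis=1), 1.0)
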