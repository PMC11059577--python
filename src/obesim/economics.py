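"""Costs, utilities, discounting and cost-effectiveness summaries.

State costs and utilities accrue against the half-cycle-corrected
occupancy; one-off event costs and disutilities accrue in the cycle the
event occurs.  Annual cycles discount at the cycle midpoint, the four
quarterly cycles at their start.  ICERs are computed from unrounded
accumulators; rounding happens only at presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from obesim.markov_engine import (
    ALIVE,
    CANCER,
    CohortTrace,
    DEAD,
    POST_ACS,
    POST_STROKE,
    PRE_T2D,
    SLEEP_APNEA,
    T2D,
)
from obesim.parameters_io import ParameterSet, UtilityModel

COST_CATEGORIES = (
    "pharmacotherapy",
    "monitoring_de",
    "bp_treatment",
    "t2d_pharmacy",
    "complication_states",
    "complication_events",
)

#: classification of the incremental point on the cost-effectiveness plane
DOMINANT, DOMINATED, NORTHEAST, SOUTHWEST, UNDEFINED = (
    "dominant", "dominated", "northeast", "southwest", "undefined")


def baseline_utility(model: UtilityModel, bmi: float, age: float,
                     male: float, cad: float, prediabetes: float,
                     hypertension: float, smoking: float) -> float:
    """Complication-free utility from the BMI regression, clipped."""
    c = model.baseline_coefficients
    u = (c.intercept + c.bmi * bmi + c.age * age + c.male * male
         + c.coronary_artery_disease * cad + c.prediabetes * prediabetes
         + c.hypertension * hypertension + c.smoking * smoking)
    return min(1.0, max(model.floor, u))


def discount_factor(rate: float, t: float) -> float:
    return (1.0 + rate) ** (-t)


def _discount_times(trace: CohortTrace) -> np.ndarray:
    """Cycle valuation times: midpoint for annual cycles, start for
    quarterly ones (consistent with half-cycle-corrected occupancy)."""
    t = np.where(trace.dt >= 0.5, trace.t_start + 0.5 * trace.dt,
                 trace.t_start)
    return t


def cycle_value(occupancy: np.ndarray, per_state_value: np.ndarray,
                event_counts: float, per_event_value: float, dt: float,
                rate: float, t_value: float) -> tuple[float, float]:
    """(discounted, undiscounted) value increment for one cycle."""
    undisc = float(occupancy @ per_state_value) * dt \
        + event_counts * per_event_value
    return undisc * discount_factor(rate, t_value), undisc


@dataclass
class ArmEconomics:
    """Discounted per-arm totals plus undiscounted LYs."""

    arm: str
    cost_categories: dict[str, float] = field(default_factory=dict)
    total_cost: float = 0.0
    qalys: float = 0.0
    life_years: float = 0.0          # discounted
    life_years_undiscounted: float = 0.0
    qalys_undiscounted: float = 0.0


def value_trace(trace: CohortTrace, params: ParameterSet) -> ArmEconomics:
    """Attach discounted costs and QALYs to a cohort trace."""
    rc = params.settings.discount_rate_costs
    re = params.settings.discount_rate_effects
    t_val = _discount_times(trace)
    dfc = (1.0 + rc) ** (-t_val)
    dfe = (1.0 + re) ** (-t_val)
    n = trace.n_cycles
    profile = params.cohort
    costs = params.costs
    util = params.utility

    alive_idx = list(ALIVE)
    alive_acc = trace.accrual[:, alive_idx].sum(axis=1)

    # ---- costs ------------------------------------------------------------
    cat = {k: 0.0 for k in COST_CATEGORIES}

    drug_py = trace.fraction_on_drug * alive_acc * trace.dt
    cat["pharmacotherapy"] = float(
        (drug_py * costs.drug_annual_cost * dfc).sum())

    monitor = costs.monitoring_annual_cost()
    cat["monitoring_de"] = float((alive_acc * trace.dt * monitor * dfc).sum())

    cat["bp_treatment"] = float(
        (alive_acc * trace.dt * profile.hypertension
         * costs.bp_treatment_annual_cost * dfc).sum())

    t2d_py = trace.accrual[:, T2D] * trace.dt
    cat["t2d_pharmacy"] = float(
        (t2d_py * costs.t2d_pharmacy_annual_cost * dfc).sum())

    sc = costs.state_annual_costs
    state_cost = np.zeros(trace.occupancy_end.shape[1])
    state_cost[SLEEP_APNEA] = sc.sleep_apnea
    state_cost[PRE_T2D] = sc.pre_t2d
    state_cost[T2D] = sc.t2d
    state_cost[POST_ACS] = sc.post_acs
    state_cost[POST_STROKE] = sc.post_stroke
    state_cost[CANCER] = sc.cancer
    cat["complication_states"] = float(
        ((trace.accrual @ state_cost) * trace.dt * dfc).sum())

    ec = costs.event_costs
    aec = costs.adverse_event_costs
    event_cost = {"mi": ec.mi, "unstable_angina": ec.unstable_angina,
                  "stroke": ec.stroke, "tia": ec.tia,
                  "knee_replacement": ec.knee_replacement,
                  "bariatric_surgery": params.bariatric.one_off_cost,
                  "severe_gi": aec.severe_gi,
                  "hypoglycemia": aec.hypoglycemia}
    ev_total = np.zeros(n)
    for ev, unit in event_cost.items():
        ev_total += trace.events[ev] * unit
    cat["complication_events"] = float((ev_total * dfc).sum())

    # ---- utilities --------------------------------------------------------
    sd = util.state_disutilities
    state_dis = np.zeros(trace.occupancy_end.shape[1])
    state_dis[SLEEP_APNEA] = sd.sleep_apnea
    state_dis[PRE_T2D] = sd.pre_t2d
    state_dis[T2D] = sd.t2d
    state_dis[POST_ACS] = sd.post_acs
    state_dis[POST_STROKE] = sd.post_stroke
    state_dis[CANCER] = sd.cancer

    ed = util.event_disutilities
    event_dis = {"mi": ed.mi, "unstable_angina": ed.unstable_angina,
                 "stroke": ed.stroke, "tia": ed.tia,
                 "knee_replacement": ed.knee_replacement,
                 "bariatric_surgery": params.bariatric.disutility,
                 "severe_gi": ed.severe_gi,
                 "hypoglycemia": ed.hypoglycemia}

    qalys_d = 0.0
    qalys_u = 0.0
    for i in range(n):
        st = trace.effective_states[i]
        age = profile.mean_age + trace.t_start[i]
        u_base = baseline_utility(
            util, st.bmi, age, profile.proportion_male,
            profile.coronary_artery_disease, profile.prediabetes,
            profile.hypertension, profile.smoking)
        per_state_u = u_base - state_dis
        per_state_u[DEAD] = 0.0
        q_cycle = float(trace.accrual[i] @ per_state_u) * trace.dt[i]
        for ev, dis in event_dis.items():
            q_cycle -= trace.events[ev][i] * dis
        qalys_u += q_cycle
        qalys_d += q_cycle * dfe[i]

    ly_u = float((alive_acc * trace.dt).sum())
    ly_d = float((alive_acc * trace.dt * dfe).sum())

    out = ArmEconomics(arm=trace.arm, cost_categories=cat,
                       total_cost=sum(cat.values()), qalys=qalys_d,
                       life_years=ly_d, life_years_undiscounted=ly_u,
                       qalys_undiscounted=qalys_u)
    return out


@dataclass
class CEResult:
    """Per-arm discounted totals, incrementals, ICER and NMB."""

    treatment: ArmEconomics
    comparator: ArmEconomics
    wtp: float
    delta_cost: float = 0.0
    delta_qalys: float = 0.0
    delta_lys: float = 0.0
    icer_per_qaly: float | None = None
    icer_per_ly: float | None = None
    classification: str = UNDEFINED
    nmb: float = 0.0

    @property
    def icer_defined(self) -> bool:
        return self.icer_per_qaly is not None and \
            math.isfinite(self.icer_per_qaly)


def icer_from_totals(cost_a: float, cost_b: float, eff_a: float,
                     eff_b: float) -> float | None:
    """ICER of strategy a vs b from unrounded totals; None if undefined."""
    d_eff = eff_a - eff_b
    if abs(d_eff) < 1e-12:
        return None
    return (cost_a - cost_b) / d_eff


def classify(delta_cost: float, delta_qalys: float) -> str:
    if abs(delta_qalys) < 1e-12 and abs(delta_cost) < 1e-12:
        return UNDEFINED
    if delta_qalys >= 0.0 and delta_cost <= 0.0:
        return DOMINANT
    if delta_qalys <= 0.0 and delta_cost >= 0.0:
        return DOMINATED
    return NORTHEAST if delta_qalys > 0.0 else SOUTHWEST


def compute_ce_result(treatment: ArmEconomics, comparator: ArmEconomics,
                      wtp: float) -> CEResult:
    """Incremental cost-effectiveness of the treated arm vs comparator.

    The ICER is left undefined (None) for identical arms and suppressed
    for dominance; the net monetary benefit is always reported.
    """
    d_cost = treatment.total_cost - comparator.total_cost
    d_q = treatment.qalys - comparator.qalys
    d_ly = treatment.life_years - comparator.life_years
    cls = classify(d_cost, d_q)
    icer_q = icer_from_totals(treatment.total_cost, comparator.total_cost,
                              treatment.qalys, comparator.qalys)
    icer_ly = icer_from_totals(treatment.total_cost, comparator.total_cost,
                               treatment.life_years, comparator.life_years)
    if cls in (DOMINANT, DOMINATED):
        icer_q = None  # quadrant convention: not reported as a negative ratio
    return CEResult(treatment=treatment, comparator=comparator, wtp=wtp,
                    delta_cost=d_cost, delta_qalys=d_q, delta_lys=d_ly,
                    icer_per_qaly=icer_q, icer_per_ly=icer_ly,
                    classification=cls, nmb=wtp * d_q - d_cost)


def run_ce_analysis(params: ParameterSet) -> CEResult:
    """Full pipeline: trajectories -> engine -> economics -> CE result."""
    from obesim.trajectories import build_arm_trajectory
    from obesim.markov_engine import run_arm

    tr_t = build_arm_trajectory(params, "treatment")
    tr_c = build_arm_trajectory(params, "comparator")
    trace_t = run_arm(params, tr_t)
    trace_c = run_arm(params, tr_c)
    econ_t = value_trace(trace_t, params)
    econ_c = value_trace(trace_c, params)
    return compute_ce_result(econ_t, econ_c, params.settings.wtp_threshold)


def ce_result_table(result: CEResult):
    """Tabular export mirroring a base-case cost-breakdown table."""
    import pandas as pd

    rows = []
    for cat in COST_CATEGORIES:
        rows.append({
            "row": cat,
            "treatment": result.treatment.cost_categories[cat],
            "comparator": result.comparator.cost_categories[cat],
            "incremental": (result.treatment.cost_categories[cat]
                            - result.comparator.cost_categories[cat])})
    rows.append({"row": "total_costs",
                 "treatment": result.treatment.total_cost,
                 "comparator": result.comparator.total_cost,
                 "incremental": result.delta_cost})
    rows.append({"row": "total_qalys", "treatment": result.treatment.qalys,
                 "comparator": result.comparator.qalys,
                 "incremental": result.delta_qalys})
    rows.append({"row": "total_lys", "treatment": result.treatment.life_years,
                 "comparator": result.comparator.life_years,
                 "incremental": result.delta_lys})
    rows.append({"row": "icer_per_qaly", "treatment": np.nan,
                 "comparator": np.nan,
                 "incremental": (result.icer_per_qaly
                                 if result.icer_per_qaly is not None
                                 else np.nan)})
    rows.append({"row": "icer_per_ly", "treatment": np.nan,
                 "comparator": np.nan,
                 "incremental": (result.icer_per_ly
                                 if result.icer_per_ly is not None
                                 else np.nan)})
    return pd.DataFrame(rows)
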