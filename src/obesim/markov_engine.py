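"""Expected-value cohort propagation through the health-state space.

The cohort moves through mutually exclusive comorbidity states ordered by
precedence (dead > post-stroke > post-ACS > cancer > T2D > pre-T2D >
sleep apnea > none) over 4 quarterly cycles followed by annual cycles.
Within each cycle the order of operations is fixed: (1) background and
disease mortality, (2) acute events with case fatality, (3) chronic-state
transitions, (4) bariatric-surgery uptake.  Each step is a row-stochastic
linear map, so every cycle's total update is recorded as a single
transition matrix per sex stratum — the same probabilities an
individual-level microsimulation would sample from.

Annual cycles use half-cycle correction: accruals are evaluated at the
mean of start- and end-of-cycle occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from obesim.parameters_io import MortalityModel, ParameterSet
from obesim.risk_engine import (
    cancer_incidence,
    evaluate_annual_probability,
    probability_rescale,
    sleep_apnea_prevalence,
)
from obesim.trajectories import TrajectoryPath, apply_bariatric_effect

# state indices, in precedence order for costing/utility
NONE, SLEEP_APNEA, PRE_T2D, T2D, POST_ACS, POST_STROKE, CANCER, DEAD = range(8)
N_STATES = 8
STATE_NAMES = ("none", "sleep_apnea", "pre_t2d", "t2d", "post_acs",
               "post_stroke", "cancer", "dead")
ALIVE = tuple(range(7))

EVENT_NAMES = ("mi", "unstable_angina", "stroke", "tia", "knee_replacement",
               "bariatric_surgery", "severe_gi", "hypoglycemia")

_ROW_SUM_TOL = 1e-10


class TransitionConsistencyError(RuntimeError):
    """A per-cycle transition matrix failed the row-sum check."""


@dataclass
class CohortTrace:
    """Per-cycle state occupancy, events and accruals for one arm."""

    arm: str
    t_start: np.ndarray          # (n_cycles,)
    dt: np.ndarray               # (n_cycles,)
    occupancy_start: np.ndarray  # (n_cycles, 8), both strata combined
    occupancy_end: np.ndarray
    accrual: np.ndarray          # half-cycle-corrected occupancy per cycle
    events: dict[str, np.ndarray]        # expected events per cohort member
    effective_states: list               # RiskFactorState per cycle
    fraction_on_drug: np.ndarray
    on_treatment: np.ndarray             # bool per cycle
    transition_matrices: dict[str, list[np.ndarray]]  # per sex stratum
    stratum_init: dict[str, np.ndarray]
    bariatric_cum: np.ndarray            # cumulative surgery mass per cycle
    strata_age0: float
    trajectory: TrajectoryPath = field(repr=False, default=None)

    @property
    def n_cycles(self) -> int:
        return len(self.dt)

    def person_years_by_state(self) -> np.ndarray:
        return (self.accrual * self.dt[:, None]).sum(axis=0)

    def alive_person_years(self) -> float:
        return float(self.person_years_by_state()[list(ALIVE)].sum())

    def life_years(self) -> float:
        return self.alive_person_years()

    def total_events(self, event: str) -> float:
        return float(self.events[event].sum())


def background_mortality(model: MortalityModel, age: float, male: bool,
                         bmi: float) -> float:
    """Annual non-disease-specific death probability, BMI-adjusted.

    All-cause q is first reduced by the fraction of deaths attributable
    to the modelled complications; the remainder is scaled on the rate
    scale by the hazard ratio per BMI unit above the reference.
    """
    q_all = model.life_table.annual_q(age, male)
    q_bg = q_all * (1.0 - model.disease_specific_fraction)
    if q_bg >= 1.0:
        return 1.0
    rate = -math.log1p(-q_bg)
    hr = model.bmi_hazard_ratio_per_unit ** (bmi - model.bmi_reference)
    return min(1.0, 1.0 - math.exp(-rate * hr))


def apply_acute_event(occupancy: float, p_event: float, case_fatality: float
                      ) -> tuple[float, float, float]:
    """Split source-state mass for one acute event.

    Returns (events, fatal_mass, survivor_mass): ``events`` is the
    expected event count, fatal mass moves to dead, survivors move to
    the event's destination state.
    """
    if not (0.0 <= p_event <= 1.0 and 0.0 <= case_fatality <= 1.0):
        raise ValueError("probabilities must be in [0, 1]")
    events = occupancy * p_event
    fatal = events * case_fatality
    return events, fatal, events - fatal


def bariatric_uptake(spec, mean_bmi: float, post_treatment: bool,
                     dt: float) -> float:
    """Per-cycle surgery probability among the surviving cohort."""
    if not post_treatment or mean_bmi < spec.bmi_eligibility_threshold:
        return 0.0
    return probability_rescale(spec.annual_incidence_post_treatment, dt)


def propagate(matrices: list[np.ndarray], occ0: np.ndarray) -> np.ndarray:
    """Pure cohort propagation: occupancy after each matrix in sequence.

    Returns an array of shape (len(matrices) + 1, n_states) whose first
    row is ``occ0``.
    """
    occ = np.asarray(occ0, dtype=float)
    out = [occ]
    for m in matrices:
        _check_rows(m)
        occ = occ @ m
        out.append(occ)
    return np.vstack(out)


def _check_rows(m: np.ndarray) -> None:
    bad = np.abs(m.sum(axis=1) - 1.0)
    if np.any(bad > 1e-8):
        raise TransitionConsistencyError(
            f"transition-matrix row sums off by up to {bad.max():.3e}")
    if np.any(m < -1e-12):
        raise TransitionConsistencyError("negative transition probability")


def _identity_rows() -> np.ndarray:
    return np.eye(N_STATES)


def _initial_occupancy(params: ParameterSet, male: bool,
                       mass: float) -> np.ndarray:
    """Allocate a sex stratum's mass to states by precedence."""
    occ = np.zeros(N_STATES)
    profile = params.cohort
    mix = profile.baseline.glycemic_mix
    occ[POST_ACS] = mass * profile.coronary_artery_disease
    rem = mass - occ[POST_ACS]
    occ[T2D] = rem * mix.t2d
    occ[PRE_T2D] = rem * mix.prediabetes
    rem2 = rem - occ[T2D] - occ[PRE_T2D]
    prev = sleep_apnea_prevalence(profile.baseline, profile.mean_age,
                                  1.0 if male else 0.0,
                                  params.risk_equations.sleep_apnea)
    occ[SLEEP_APNEA] = rem2 * prev
    occ[NONE] = rem2 - occ[SLEEP_APNEA]
    return occ


def _mortality_matrix(params: ParameterSet, age: float, male: bool,
                      bmi: float, dt: float) -> np.ndarray:
    q_annual = background_mortality(params.mortality, age, male, bmi)
    base_rate = -math.log1p(-min(q_annual, 1.0 - 1e-15))
    hrs = params.mortality.post_event_hazard_ratios
    state_hr = np.ones(N_STATES)
    state_hr[T2D] = hrs.t2d
    state_hr[POST_ACS] = hrs.post_acs
    state_hr[POST_STROKE] = hrs.post_stroke
    m = _identity_rows()
    for s in ALIVE:
        q = 1.0 - math.exp(-base_rate * state_hr[s] * dt)
        m[s, s] = 1.0 - q
        m[s, DEAD] = q
    return m


def _acute_event_matrix(params: ParameterSet, state, age: float, male: bool,
                        dt: float, p_bariatric: float
                        ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Matrix for CV events, knee replacement and bariatric surgery.

    Also returns, per event, the per-source-state event probability so
    expected counts can be accumulated against pre-step occupancy.
    """
    eqs = params.risk_equations
    sexf = 1.0 if male else 0.0
    p_first = probability_rescale(
        evaluate_annual_probability(eqs.cv_first, state, age, sexf), dt)
    p_recur = probability_rescale(
        evaluate_annual_probability(eqs.cv_recurrent, state, age, sexf), dt)
    p_knee = probability_rescale(
        evaluate_annual_probability(eqs.knee_replacement, state, age, sexf),
        dt)
    split = eqs.cv_event_split
    cf = params.mortality.case_fatality

    cv_events = {"mi": (split.mi, cf.mi, POST_ACS),
                 "unstable_angina": (split.unstable_angina,
                                     cf.unstable_angina, POST_ACS),
                 "stroke": (split.stroke, cf.stroke, POST_STROKE),
                 "tia": (split.tia, cf.tia, POST_STROKE)}

    m = _identity_rows()
    probs: dict[str, np.ndarray] = {e: np.zeros(N_STATES)
                                    for e in EVENT_NAMES}
    for s in ALIVE:
        p_cv = p_recur if s in (POST_ACS, POST_STROKE) else p_first
        for ev, (frac, cfe, dest) in cv_events.items():
            p_e = p_cv * frac
            probs[ev][s] = p_e
            # post-stroke precedence: recurrent coronary events do not
            # demote the post-stroke sub-cohort
            dest_s = dest if not (s == POST_STROKE and dest == POST_ACS) \
                else POST_STROKE
            m[s, s] -= p_e
            m[s, DEAD] += p_e * cfe
            m[s, dest_s] += p_e * (1.0 - cfe)
        # transient events: no state change, only case fatality
        for ev, p_e, cfe in (("knee_replacement", p_knee,
                              cf.knee_replacement),
                             ("bariatric_surgery", p_bariatric,
                              params.bariatric.case_fatality)):
            probs[ev][s] = p_e
            m[s, s] -= p_e * cfe
            m[s, DEAD] += p_e * cfe
    return m, probs


def _chronic_matrix(params: ParameterSet, state, age: float, male: bool,
                    dt: float, occ_pre: np.ndarray
                    ) -> np.ndarray:
    """Chronic incidence plus prevalence rebalancing.

    T2D and cancer incidence move mass up the hierarchy; the
    prediabetes/NGT split and the sleep-apnea share are then rebalanced
    toward the trajectory-driven (glycemic mix) and equation-driven
    (logistic prevalence) targets within the low-precedence pool.
    """
    eqs = params.risk_equations
    sexf = 1.0 if male else 0.0
    p_t2d = probability_rescale(
        evaluate_annual_probability(eqs.t2d, state, age, sexf), dt)
    # combined incidence over cancer sites (independent-cause composition)
    surv = 1.0
    for spec in eqs.cancers.values():
        p_c = cancer_incidence(spec, state, age, male,
                               params.cohort.menopause_age)
        surv *= 1.0 - probability_rescale(p_c, dt)
    p_cancer = 1.0 - surv

    m = _identity_rows()
    for s in (NONE, SLEEP_APNEA, PRE_T2D):
        m[s, s] -= p_t2d
        m[s, T2D] += p_t2d
    for s in (NONE, SLEEP_APNEA, PRE_T2D, T2D):
        stay = m[s, s]
        m[s, CANCER] += stay * p_cancer
        m[s, s] = stay * (1.0 - p_cancer)

    occ_mid = occ_pre @ m

    # glycemic rebalancing within {none, sleep apnea, pre-T2D}
    mix = state.glycemic_mix
    pool = occ_mid[NONE] + occ_mid[SLEEP_APNEA] + occ_mid[PRE_T2D]
    denom = mix.ngt + mix.prediabetes
    if pool > 1e-15 and denom > 1e-12:
        target_pre = pool * (mix.prediabetes / denom)
        cur_pre = occ_mid[PRE_T2D]
        reb = _identity_rows()
        if target_pre > cur_pre + 1e-15:
            need = target_pre - cur_pre
            low = occ_mid[NONE] + occ_mid[SLEEP_APNEA]
            f = min(1.0, need / low) if low > 1e-15 else 0.0
            for s in (NONE, SLEEP_APNEA):
                reb[s, s] -= f
                reb[s, PRE_T2D] += f
        elif cur_pre > target_pre + 1e-15:
            f = min(1.0, (cur_pre - target_pre) / cur_pre)
            low = occ_mid[NONE] + occ_mid[SLEEP_APNEA]
            if low > 1e-15:
                w_sa = occ_mid[SLEEP_APNEA] / low
            else:
                w_sa = sleep_apnea_prevalence(state, age, sexf,
                                              eqs.sleep_apnea)
            reb[PRE_T2D, PRE_T2D] -= f
            reb[PRE_T2D, SLEEP_APNEA] += f * w_sa
            reb[PRE_T2D, NONE] += f * (1.0 - w_sa)
        m = m @ reb
        occ_mid = occ_pre @ m

    # sleep-apnea prevalence rebalancing within {none, sleep apnea}
    prev = sleep_apnea_prevalence(state, age, sexf, eqs.sleep_apnea)
    pool = occ_mid[NONE] + occ_mid[SLEEP_APNEA]
    if pool > 1e-15:
        target_sa = pool * prev
        reb = _identity_rows()
        if target_sa > occ_mid[SLEEP_APNEA] + 1e-15 and occ_mid[NONE] > 1e-15:
            f = min(1.0, (target_sa - occ_mid[SLEEP_APNEA]) / occ_mid[NONE])
            reb[NONE, NONE] -= f
            reb[NONE, SLEEP_APNEA] += f
        elif occ_mid[SLEEP_APNEA] > target_sa + 1e-15:
            f = min(1.0, (occ_mid[SLEEP_APNEA] - target_sa)
                    / occ_mid[SLEEP_APNEA])
            reb[SLEEP_APNEA, SLEEP_APNEA] -= f
            reb[SLEEP_APNEA, NONE] += f
        m = m @ reb
    return m


def _effective_state(traj_state, params: ParameterSet,
                     surgeries: list[tuple[float, float]], t_end: float,
                     alive: float):
    """Cohort-mean risk-factor state after bariatric-surgery effects."""
    if not surgeries or alive <= 1e-12:
        return traj_state
    spec = params.bariatric
    w_total = 0.0
    post = {"bmi": 0.0, "sbp": 0.0, "tc": 0.0, "hdl": 0.0}
    for t_s, mass in surgeries:
        w = min(1.0, mass / alive)
        st = apply_bariatric_effect(traj_state, spec, max(0.0, t_end - t_s))
        post["bmi"] += w * st.bmi
        post["sbp"] += w * st.sbp
        post["tc"] += w * st.total_cholesterol
        post["hdl"] += w * st.hdl
        w_total += w
    w_total = min(1.0, w_total)
    if w_total <= 0.0:
        return traj_state
    # renormalise the per-surgery average then mix with the rest
    scale = (w_total / sum(min(1.0, m / alive) for _, m in surgeries))
    from obesim.parameters_io import RiskFactorState
    bmi = (1 - w_total) * traj_state.bmi + post["bmi"] * scale
    sbp = (1 - w_total) * traj_state.sbp + post["sbp"] * scale
    tc = (1 - w_total) * traj_state.total_cholesterol + post["tc"] * scale
    hdl = (1 - w_total) * traj_state.hdl + post["hdl"] * scale
    hdl = min(hdl, tc - 1e-6)
    return RiskFactorState(bmi=max(18.5, bmi), sbp=max(60.0, sbp),
                           total_cholesterol=max(0.5, tc),
                           hdl=max(0.1, hdl),
                           glycemic_mix=traj_state.glycemic_mix)


def run_arm(params: ParameterSet, trajectory: TrajectoryPath) -> CohortTrace:
    """Run one arm's cohort over the full horizon."""
    n = len(trajectory)
    horizon_cycles = 4 + (params.settings.horizon_years - 1)
    if n < horizon_cycles:
        raise ValueError("trajectory does not cover the model horizon")

    profile = params.cohort
    strata = {"male": (True, profile.proportion_male),
              "female": (False, 1.0 - profile.proportion_male)}
    occ = {name: _initial_occupancy(params, male, mass)
           for name, (male, mass) in strata.items()}
    stratum_init = {k: v.copy() for k, v in occ.items()}
    mats: dict[str, list[np.ndarray]] = {k: [] for k in strata}

    occupancy_start = np.zeros((n, N_STATES))
    occupancy_end = np.zeros((n, N_STATES))
    accrual = np.zeros((n, N_STATES))
    events = {e: np.zeros(n) for e in EVENT_NAMES}
    eff_states = []
    bariatric_cum = np.zeros(n)
    surgeries: list[tuple[float, float]] = []

    t_start = np.array([c.t_start for c in trajectory[:n]])
    dts = np.array([c.dt for c in trajectory[:n]])
    on_rx = np.array([c.on_treatment for c in trajectory[:n]])
    on_drug = np.array([c.fraction_on_drug for c in trajectory[:n]])

    for i, cyc in enumerate(trajectory.cycles[:n]):
        age = profile.mean_age + cyc.t_start
        occ_comb0 = sum(occ.values())
        alive0 = occ_comb0[list(ALIVE)].sum()
        state = _effective_state(cyc.state, params, surgeries, cyc.t_start,
                                 max(alive0, 1e-12))
        eff_states.append(state)
        occupancy_start[i] = occ_comb0

        p_bar = bariatric_uptake(params.bariatric, state.bmi,
                                 post_treatment=not cyc.on_treatment,
                                 dt=cyc.dt)
        cycle_surgery_mass = 0.0
        for name, (male, _mass) in strata.items():
            o0 = occ[name]
            m_mort = _mortality_matrix(params, age, male, state.bmi, cyc.dt)
            o1 = o0 @ m_mort
            m_evt, probs = _acute_event_matrix(params, state, age, male,
                                               cyc.dt, p_bar)
            for ev in ("mi", "unstable_angina", "stroke", "tia",
                       "knee_replacement", "bariatric_surgery"):
                events[ev][i] += float(o1 @ probs[ev])
            cycle_surgery_mass += float(o1 @ probs["bariatric_surgery"]) \
                * (1.0 - params.bariatric.case_fatality)
            o2 = o1 @ m_evt
            m_chr = _chronic_matrix(params, state, age, male, cyc.dt, o2)
            m_total = m_mort @ m_evt @ m_chr
            _check_rows(m_total)
            mats[name].append(m_total)
            occ[name] = o0 @ m_total

        if cycle_surgery_mass > 0.0:
            surgeries.append((cyc.t_end, cycle_surgery_mass))
        bariatric_cum[i] = sum(m for _, m in surgeries)

        occ_comb1 = sum(occ.values())
        occupancy_end[i] = occ_comb1
        # treatment-related adverse events: rate per patient-year on drug
        alive_mid = 0.5 * (occ_comb0 + occ_comb1)[list(ALIVE)].sum()
        on_drug_py = cyc.fraction_on_drug * alive_mid * cyc.dt
        ae = params.treatment_effects.adverse_event_rates \
            if trajectory.arm == "treatment" \
            else params.comparator_effects.adverse_event_rates
        events["severe_gi"][i] = ae.severe_gi * on_drug_py
        events["hypoglycemia"][i] = ae.hypoglycemia * on_drug_py

        if cyc.dt >= 0.5:  # annual cycle: half-cycle correction
            accrual[i] = 0.5 * (occ_comb0 + occ_comb1)
        else:
            accrual[i] = occ_comb1

    return CohortTrace(
        arm=trajectory.arm, t_start=t_start, dt=dts,
        occupancy_start=occupancy_start, occupancy_end=occupancy_end,
        accrual=accrual, events=events, effective_states=eff_states,
        fraction_on_drug=on_drug, on_treatment=on_rx,
        transition_matrices=mats, stratum_init=stratum_init,
        bariatric_cum=bariatric_cum, strata_age0=profile.mean_age,
        trajectory=trajectory)


def event_rate_per_100py(trace: CohortTrace, event: str) -> float:
    """Expected events per 100 patient-years alive (undiscounted)."""
    py = trace.alive_person_years()
    if py <= 0.0:
        raise ZeroDivisionError("zero person-years in trace")
    return 100.0 * trace.total_events(event) / py


def trace_table(trace: CohortTrace):
    """Per-cycle tabular export of occupancy and events."""
    import pandas as pd

    rows = []
    for i in range(trace.n_cycles):
        row = {"arm": trace.arm, "cycle": i + 1,
               "t_start": trace.t_start[i], "dt": trace.dt[i]}
        for s, name in enumerate(STATE_NAMES):
            row[f"occ_{name}"] = trace.occupancy_end[i, s]
        for e in EVENT_NAMES:
            row[f"events_{e}"] = trace.events[e][i]
        row["bmi_effective"] = trace.effective_states[i].bmi
        rows.append(row)
    return pd.DataFrame(rows)
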