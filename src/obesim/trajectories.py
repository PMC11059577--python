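"""Per-cycle risk-factor trajectories for each treatment arm.

The model runs quarterly cycles in the first year and annual cycles
thereafter.  Trial effects are applied as the value reached by the end of
a cycle: the full-sample week-28 effect at the end of cycle 2, the
responder-subset week-68 effect at the end of cycle 4 (linearly
interpolated within the first year).  In the second model year the
early-responder waning ratio scales the week-68 effect; from year 3 the
full-analysis-set ratio compounds yearly while on treatment.  After the
treatment stops a catch-up schedule closes the gap to the reference path
(baseline or the lifestyle-comparator trajectory), after which natural
weight gain resumes up to a maximum age.

Patients failing the >=5% weight-loss response criterion at week 28 stop
drug at the start of cycle 3 and inherit the comparator arm's trajectory;
the two sub-cohorts are merged at the risk-factor level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from obesim.parameters_io import (
    CatchUpReference,
    CatchUpSpec,
    CohortProfile,
    GlycemicMix,
    NaturalProgression,
    ParameterSet,
    RiskFactorState,
    TreatmentEffectSchedule,
    WaningSpec,
    BariatricSpec,
)

BMI_FLOOR = 18.5

Arm = Literal["treatment", "comparator"]


@dataclass(frozen=True)
class TrajectoryCycle:
    index: int                 # 1-based cycle index
    t_start: float             # years from model start
    dt: float                  # cycle length in years (0.25 or 1.0)
    state: RiskFactorState
    on_treatment: bool
    fraction_discontinued: float
    fraction_on_drug: float

    @property
    def t_end(self) -> float:
        return self.t_start + self.dt

    @property
    def t_mid(self) -> float:
        return self.t_start + 0.5 * self.dt


@dataclass
class TrajectoryPath:
    arm: str
    cycles: list[TrajectoryCycle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    def __getitem__(self, i: int) -> TrajectoryCycle:
        return self.cycles[i]


def cycle_grid(horizon_years: int) -> list[tuple[int, float, float]]:
    """(index, t_start, dt) tuples: 4 quarterly cycles then annual ones."""
    grid = [(i + 1, 0.25 * i, 0.25) for i in range(4)]
    grid += [(5 + k, 1.0 + k, 1.0) for k in range(horizon_years - 1)]
    return grid


def apply_waning(effect_at_week68: float, ratio: float,
                 held_constant: bool = False) -> float:
    """Scale a week-68 change-from-baseline by a waning ratio."""
    if ratio < 0.0:
        raise ValueError(f"waning ratio must be >= 0, got {ratio}")
    if held_constant:
        return effect_at_week68
    return effect_at_week68 * ratio


def apply_catch_up(current: float, reference: float, spec: CatchUpSpec,
                   years_since_stop: float) -> float:
    """Close part of the (value-at-stop -> reference) gap.

    ``current`` is the value at treatment stop; the cumulative fraction
    for ``years_since_stop`` determines how much of the gap to the
    reference has been closed.  After the schedule completes the
    reference is returned exactly.
    """
    if years_since_stop < 0.0:
        raise ValueError("years_since_stop must be >= 0")
    frac = spec.cumulative_fraction(years_since_stop)
    if frac >= 1.0:
        return reference
    return current + frac * (reference - current)


def natural_weight_gain(profile: CohortProfile, age: float,
                        progression: NaturalProgression) -> float:
    """Sex-mix-weighted weight gain (kg/year); zero past the maximum age."""
    if age < 0.0:
        raise ValueError("age must be >= 0")
    if age >= progression.max_age_for_gain:
        return 0.0
    w = profile.proportion_male
    return (w * progression.weight_gain_per_year_male
            + (1.0 - w) * progression.weight_gain_per_year_female)


def apply_bariatric_effect(state: RiskFactorState, spec: BariatricSpec,
                           years_since_surgery: float) -> RiskFactorState:
    """Risk-factor state of the post-surgery sub-cohort.

    BMI falls by the durability-schedule fraction; SBP and lipids by the
    fixed absolute effects.  The glycemic mix is untouched here.
    """
    frac = spec.bmi_reduction_fraction(years_since_surgery)
    bmi = max(BMI_FLOOR, state.bmi * (1.0 - frac))
    sbp = max(60.0, state.sbp - spec.sbp_reduction)
    tc = max(0.5, state.total_cholesterol - spec.tc_reduction)
    hdl = min(tc - 1e-6, state.hdl + spec.hdl_increase)
    return RiskFactorState(bmi=bmi, sbp=sbp, total_cholesterol=tc, hdl=hdl,
                           glycemic_mix=state.glycemic_mix)


def prediabetes_reversal(mix: GlycemicMix, reversal_proportion: float,
                         persistence: float) -> GlycemicMix:
    """Move a (persistence-scaled) share of prediabetes mass to NGT.

    ``persistence`` is 1 in the cycles where the full trial effect
    applies, follows the glycemic waning ratio while on treatment, and
    unwinds with the catch-up schedule after cessation (0 = baseline mix
    restored).
    """
    moved = reversal_proportion * persistence * mix.prediabetes
    return GlycemicMix(ngt=mix.ngt + moved,
                       prediabetes=mix.prediabetes - moved,
                       t2d=mix.t2d)


# --- internal stream machinery ---------------------------------------------

_FACTORS = ("weight", "sbp", "tc", "hdl", "glycemic")

_CHANGE_FIELDS = {"weight": "relative_weight_change", "sbp": "sbp_change",
                  "tc": "tc_change", "hdl": "hdl_change"}
_HELD_ALIASES = {"tc": "total_cholesterol", "hdl": "hdl",
                 "weight": "weight", "sbp": "sbp", "glycemic": "glycemic"}


def _waning_ratio(waning: WaningSpec, factor: str, early: bool) -> float:
    if _HELD_ALIASES[factor] in waning.held_constant:
        return 1.0
    ratios = waning.early_responder if early else waning.full_analysis_set
    if factor in ("tc", "hdl"):
        # lipids not covered by the waning ratios; held flat by default
        return 1.0
    key = {"weight": "weight", "sbp": "sbp", "glycemic": "glycemic"}[factor]
    return getattr(ratios, key)


def _effect_stream(schedule: TreatmentEffectSchedule, waning: WaningSpec,
                   catch_up: CatchUpSpec, grid, use_responder: bool,
                   reference_changes: list[dict[str, float]] | None,
                   ) -> list[dict[str, float]]:
    """Per-cycle change-from-baseline for one efficacy stream.

    Returns one dict per cycle: {weight, sbp, tc, hdl, glycemic}; weight
    relative, sbp/tc/hdl absolute, glycemic the reversal persistence in
    [0, 1].  ``reference_changes`` supplies the catch-up target per cycle
    (None = baseline, i.e. zero change).
    """
    duration = schedule.treatment_duration_years
    e28f = schedule.week28_full
    e68f = schedule.week68_full
    e28 = schedule.week28_responder if use_responder else e28f
    e68 = schedule.week68_responder if use_responder else e68f

    out: list[dict[str, float]] = []
    prev: dict[str, float] = {f: 0.0 for f in _FACTORS}
    at_stop: dict[str, float] | None = None
    for idx, t_start, dt in grid:
        t_end = t_start + dt
        on_treatment = t_end <= duration + 1e-9
        cur: dict[str, float] = {}
        if on_treatment:
            for f in _FACTORS:
                if f == "glycemic":
                    cur[f] = 0.0 if idx == 1 else 1.0
                    if idx >= 5:
                        r = _waning_ratio(waning, f, early=(idx == 5))
                        cur[f] = min(1.0, prev[f] * r if idx > 5
                                     else 1.0 * r)
                    continue
                fld = _CHANGE_FIELDS[f]
                v28f, v68f = getattr(e28f, fld), getattr(e68f, fld)
                v28, v68 = getattr(e28, fld), getattr(e68, fld)
                if idx == 1:
                    cur[f] = 0.5 * v28f
                elif idx == 2:
                    cur[f] = v28f
                elif idx == 3:
                    cur[f] = 0.5 * (v28 + v68)
                elif idx == 4:
                    cur[f] = v68
                elif idx == 5:
                    cur[f] = apply_waning(v68, _waning_ratio(waning, f, True))
                else:
                    cur[f] = apply_waning(prev[f],
                                          _waning_ratio(waning, f, False))
        else:
            if at_stop is None:
                at_stop = dict(prev)
            years_since_stop = t_end - duration
            for f in _FACTORS:
                ref = 0.0
                if reference_changes is not None and f != "glycemic":
                    ref = reference_changes[idx - 1][f]
                cur[f] = apply_catch_up(at_stop[f], ref, catch_up,
                                        years_since_stop)
        out.append(cur)
        prev = cur
    return out


def _stream_to_states(changes: list[dict[str, float]],
                      schedule: TreatmentEffectSchedule,
                      profile: CohortProfile,
                      progression: NaturalProgression,
                      catch_up: CatchUpSpec, grid,
                      ) -> list[RiskFactorState]:
    """Turn change-from-baseline streams into absolute risk-factor states.

    Natural weight gain accrues once the post-cessation catch-up has
    completed, integrating the sex-mixed slope until the maximum age.
    """
    base = profile.baseline
    duration = schedule.treatment_duration_years
    catchup_years = len(catch_up.cumulative_fractions)
    t_complete = duration + catchup_years
    h2 = profile.mean_height_m ** 2

    states = []
    for (idx, t_start, dt), ch in zip(grid, changes):
        t_end = t_start + dt
        # integrated natural gain in kg from catch-up completion to t_end,
        # capped at the age where gain stops
        gain_kg = 0.0
        if t_end > t_complete:
            t_age_cap = progression.max_age_for_gain - profile.mean_age
            lo, hi = t_complete, min(t_end, max(t_complete, t_age_cap))
            if hi > lo:
                gain_kg = natural_weight_gain(
                    profile, profile.mean_age, progression) * (hi - lo)
        bmi = base.bmi * (1.0 + ch["weight"]) + gain_kg / h2
        bmi = max(BMI_FLOOR, bmi)
        tc = max(0.5, base.total_cholesterol + ch["tc"])
        hdl = max(0.1, base.hdl + ch["hdl"])
        hdl = min(hdl, tc - 1e-6)
        mix = prediabetes_reversal(
            base.glycemic_mix, schedule.prediabetes_reversal_proportion,
            ch["glycemic"])
        states.append(RiskFactorState(
            bmi=bmi, sbp=max(60.0, base.sbp + ch["sbp"]),
            total_cholesterol=tc, hdl=hdl, glycemic_mix=mix))
    return states


def _mix_states(a: RiskFactorState, b: RiskFactorState,
                w: float) -> RiskFactorState:
    """Occupancy-weighted merge of two sub-cohort states (w = weight of a)."""
    mix = GlycemicMix(
        ngt=w * a.glycemic_mix.ngt + (1 - w) * b.glycemic_mix.ngt,
        prediabetes=(w * a.glycemic_mix.prediabetes
                     + (1 - w) * b.glycemic_mix.prediabetes),
        t2d=w * a.glycemic_mix.t2d + (1 - w) * b.glycemic_mix.t2d)
    return RiskFactorState(
        bmi=w * a.bmi + (1 - w) * b.bmi,
        sbp=w * a.sbp + (1 - w) * b.sbp,
        total_cholesterol=(w * a.total_cholesterol
                           + (1 - w) * b.total_cholesterol),
        hdl=w * a.hdl + (1 - w) * b.hdl,
        glycemic_mix=mix)


def build_arm_trajectory(params: ParameterSet, arm: Arm) -> TrajectoryPath:
    """Produce the per-cycle risk-factor path for one arm.

    The comparator follows its full-sample lifestyle effect, wanes,
    catches up to baseline and then gains weight naturally.  The treated
    arm mixes the responder stream (full effect, waning, catch-up) with
    the non-responder fraction, which is switched to the comparator path
    from cycle 3 by the stopping rule.
    """
    if arm not in ("treatment", "comparator"):
        raise ValueError(f"unknown arm {arm!r}")
    grid = cycle_grid(params.settings.horizon_years)
    profile = params.cohort

    comp_sched = params.comparator_effects
    comp_changes = _effect_stream(comp_sched, params.waning, params.catch_up,
                                  grid, use_responder=False,
                                  reference_changes=None)
    comp_states = _stream_to_states(comp_changes, comp_sched, profile,
                                    params.natural_progression,
                                    params.catch_up, grid)

    if arm == "comparator":
        cycles = [TrajectoryCycle(index=i, t_start=t0, dt=dt, state=s,
                                  on_treatment=t0 + dt <= comp_sched.
                                  treatment_duration_years + 1e-9,
                                  fraction_discontinued=0.0,
                                  fraction_on_drug=0.0)
                  for (i, t0, dt), s in zip(grid, comp_states)]
        return TrajectoryPath(arm=arm, cycles=cycles)

    sched = params.treatment_effects
    ref = comp_changes if (params.catch_up.reference
                           is CatchUpReference.d_and_e_trajectory) else None
    use_resp = params.stopping_rule
    treat_changes = _effect_stream(sched, params.waning, params.catch_up,
                                   grid, use_responder=use_resp,
                                   reference_changes=ref)
    treat_states = _stream_to_states(treat_changes, sched, profile,
                                     params.natural_progression,
                                     params.catch_up, grid)

    p_resp = sched.responder_proportion
    duration = sched.treatment_duration_years
    cycles = []
    for (i, t0, dt), s_t, s_c in zip(grid, treat_states, comp_states):
        on_rx = t0 + dt <= duration + 1e-9
        if params.stopping_rule and i >= 3:
            state = _mix_states(s_t, s_c, p_resp)
            frac_disc = 1.0 - p_resp
            on_drug = p_resp if on_rx else 0.0
        else:
            state = s_t
            frac_disc = 0.0
            on_drug = 1.0 if on_rx else 0.0
        cycles.append(TrajectoryCycle(
            index=i, t_start=t0, dt=dt, state=state, on_treatment=on_rx,
            fraction_discontinued=frac_disc, fraction_on_drug=on_drug))
    return TrajectoryPath(arm=arm, cycles=cycles)


def trajectory_table(paths: list[TrajectoryPath]):
    """Tabular export (one row per cycle per arm) for BMI-curve plotting."""
    import pandas as pd

    rows = []
    for path in paths:
        for c in path:
            rows.append({
                "arm": path.arm, "cycle": c.index, "t_start": c.t_start,
                "dt": c.dt, "bmi": c.state.bmi, "sbp": c.state.sbp,
                "total_cholesterol": c.state.total_cholesterol,
                "hdl": c.state.hdl,
                "ngt": c.state.glycemic_mix.ngt,
                "prediabetes": c.state.glycemic_mix.prediabetes,
                "t2d": c.state.glycemic_mix.t2d,
                "on_treatment": c.on_treatment,
                "fraction_discontinued": c.fraction_discontinued,
                "fraction_on_drug": c.fraction_on_drug,
            })
    return pd.DataFrame(rows)
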