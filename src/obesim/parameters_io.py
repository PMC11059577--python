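"""Domain types, validation, and I/O for model parameter sets.

All model inputs — cohort profile, treatment-effect schedules, waning,
catch-up, risk-equation coefficient tables, life table, utilities, costs
and economic settings — are bundled into a single :class:`ParameterSet`,
which is the unit of scenario overlay and probabilistic perturbation.

Files are YAML with a ``schema_version`` key.  Proportions are stored as
fractions in [0, 1]; percent appears only at the reporting boundary.
Currency values are plain decimals tagged with ``currency_year``.
"""

from __future__ import annotations

import copy
import math
from enum import Enum
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_validator,
    model_validator,
)

SCHEMA_VERSION = 1

GLYCEMIC_STATES = ("ngt", "prediabetes", "t2d")

#: Acute transient events recognised throughout the model.
ACUTE_EVENTS = ("mi", "unstable_angina", "stroke", "tia",
                "knee_replacement", "bariatric_surgery")


class StrictModel(BaseModel):
    """Base model: unknown keys rejected, values validated on assignment."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class EconomicSettings(StrictModel):
    discount_rate_costs: float = Field(ge=0.0, lt=1.0)
    discount_rate_effects: float = Field(ge=0.0, lt=1.0)
    horizon_years: int = Field(ge=1)
    wtp_threshold: float = Field(gt=0.0)
    currency_year: int = Field(ge=1900, le=2100)


class GlycemicMix(StrictModel):
    """Cohort fractions by glucose-tolerance status; must sum to 1."""

    ngt: float = Field(ge=0.0, le=1.0)
    prediabetes: float = Field(ge=0.0, le=1.0)
    t2d: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "GlycemicMix":
        total = self.ngt + self.prediabetes + self.t2d
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"glycemic mix must sum to 1, got {total!r}")
        return self

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ngt, self.prediabetes, self.t2d)


class RiskFactorState(StrictModel):
    """The cohort's surrogate endpoints at one point in time.

    These four risk factors plus the glycemic-status mix drive every risk
    equation in the model.
    """

    bmi: float = Field(gt=10.0, lt=100.0)
    sbp: float = Field(gt=50.0, lt=300.0)
    total_cholesterol: float = Field(gt=0.0)
    hdl: float = Field(gt=0.0)
    glycemic_mix: GlycemicMix

    @model_validator(mode="after")
    def _hdl_below_tc(self) -> "RiskFactorState":
        if self.hdl >= self.total_cholesterol:
            raise ValueError(
                f"hdl ({self.hdl}) must be below total cholesterol "
                f"({self.total_cholesterol})"
            )
        return self


class CohortProfile(StrictModel):
    mean_age: float = Field(ge=18.0, le=100.0)
    proportion_male: float = Field(ge=0.0, le=1.0)
    mean_height_m: float = Field(gt=1.0, lt=2.5)
    baseline: RiskFactorState
    hypertension: float = Field(ge=0.0, le=1.0)
    prediabetes: float = Field(ge=0.0, le=1.0)
    coronary_artery_disease: float = Field(ge=0.0, le=1.0)
    smoking: float = Field(ge=0.0, le=1.0)
    menopause_age: float = Field(ge=30.0, le=70.0)


class RiskFactorChange(StrictModel):
    """Change from baseline at one trial timepoint.

    Weight is carried as a relative change (e.g. −0.149 for −14.9%); the
    remaining factors are absolute changes in their native units.
    """

    relative_weight_change: float = Field(ge=-0.9, le=0.5)
    sbp_change: float = Field(ge=-80.0, le=80.0)
    tc_change: float = Field(ge=-5.0, le=5.0)
    hdl_change: float = Field(ge=-2.0, le=2.0)


class AdverseEventRates(StrictModel):
    """Treatment-emergent adverse events, events per patient-year on drug."""

    severe_gi: float = Field(ge=0.0)
    hypoglycemia: float = Field(ge=0.0)


class TreatmentEffectSchedule(StrictModel):
    """Trial-derived change-from-baseline at weeks 28 and 68 for one arm."""

    week28_full: RiskFactorChange
    week68_full: RiskFactorChange
    week28_responder: RiskFactorChange
    week68_responder: RiskFactorChange
    responder_proportion: float = Field(ge=0.0, le=1.0)
    prediabetes_reversal_proportion: float = Field(ge=0.0, le=1.0)
    treatment_duration_years: int = Field(ge=1)
    adverse_event_rates: AdverseEventRates

    @model_validator(mode="after")
    def _responders_hit_criterion(self) -> "TreatmentEffectSchedule":
        # the responder definition is >= 5% weight loss; responder-subset
        # week-68 efficacy below that would be internally inconsistent
        if self.responder_proportion < 1.0 - 1e-12:
            if self.week68_responder.relative_weight_change > -0.05:
                raise ValueError(
                    "responder-subset week-68 weight change must be <= -5%"
                )
        return self


class WaningRatios(StrictModel):
    """Week-104 / week-68 change ratios for the waning factors."""

    weight: float = Field(ge=0.0)
    sbp: float = Field(ge=0.0)
    glycemic: float = Field(ge=0.0)


class WaningSpec(StrictModel):
    """Attenuation of trial effects beyond the trial horizon.

    ``early_responder`` ratios apply in the second model year; the
    full-analysis-set ratios compound yearly thereafter while on
    treatment.  Total cholesterol and HDL are held constant (ratio 1)
    because they were not re-assessed at the later timepoint.
    """

    early_responder: WaningRatios
    full_analysis_set: WaningRatios
    held_constant: tuple[str, ...] = ("total_cholesterol", "hdl")

    @field_validator("held_constant")
    @classmethod
    def _known_factors(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        known = {"total_cholesterol", "hdl", "weight", "sbp", "glycemic"}
        for f in v:
            if f not in known:
                raise ValueError(f"unknown held-constant factor {f!r}")
        return tuple(v)


class CatchUpReference(str, Enum):
    baseline_value = "baseline_value"
    d_and_e_trajectory = "d_and_e_trajectory"


class CatchUpSpec(StrictModel):
    """Post-cessation return of risk factors toward a reference path.

    ``cumulative_fractions[k]`` is the fraction of the gap (between the
    value at treatment stop and the reference) closed by the end of year
    k+1 after stopping.  ``[1.0]`` means full return after one year.
    """

    cumulative_fractions: tuple[float, ...] = (1.0,)
    reference: CatchUpReference = CatchUpReference.baseline_value

    @field_validator("cumulative_fractions")
    @classmethod
    def _monotone_complete(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not v:
            raise ValueError("catch-up schedule must not be empty")
        prev = 0.0
        for f in v:
            if f < prev - 1e-12 or f < 0.0 or f > 1.0:
                raise ValueError(
                    "catch-up fractions must be non-decreasing in [0, 1]"
                )
            prev = f
        if abs(v[-1] - 1.0) > 1e-12:
            raise ValueError("catch-up schedule must end at 1.0")
        return tuple(v)

    def cumulative_fraction(self, years_since_stop: float) -> float:
        if years_since_stop <= 0.0:
            return 0.0
        idx = max(1, math.ceil(years_since_stop - 1e-12))
        if idx >= len(self.cumulative_fractions):
            return 1.0
        return self.cumulative_fractions[idx - 1]


class NaturalProgression(StrictModel):
    weight_gain_per_year_male: float = Field(ge=0.0)
    weight_gain_per_year_female: float = Field(ge=0.0)
    max_age_for_gain: float = Field(le=120.0)


class BariatricSpec(StrictModel):
    """Bariatric surgery as next-line therapy after pharmacotherapy stops."""

    annual_incidence_post_treatment: float = Field(ge=0.0, le=1.0)
    bmi_eligibility_threshold: float = Field(gt=30.0)
    bmi_reduction_year1: float = Field(ge=0.0, le=1.0)
    bmi_reduction_longrun: float = Field(ge=0.0, le=1.0)
    sbp_reduction: float = Field(ge=0.0)
    tc_reduction: float = Field(ge=0.0)
    hdl_increase: float = Field(ge=0.0)
    case_fatality: float = Field(ge=0.0, le=1.0)
    one_off_cost: float = Field(ge=0.0)
    disutility: float = Field(ge=0.0)

    def bmi_reduction_fraction(self, years_since_surgery: float) -> float:
        """Relative BMI reduction at a given time after surgery."""
        if years_since_surgery < 0.0:
            raise ValueError("years_since_surgery must be >= 0")
        if years_since_surgery < 1.0:
            return self.bmi_reduction_year1
        return self.bmi_reduction_longrun


class LifeTable(StrictModel):
    """Annual all-cause death probabilities by single year of age and sex."""

    ages: tuple[int, ...]
    q_male: tuple[float, ...]
    q_female: tuple[float, ...]

    @model_validator(mode="after")
    def _consistent(self) -> "LifeTable":
        if not (len(self.ages) == len(self.q_male) == len(self.q_female)):
            raise ValueError("life table columns must have equal length")
        if list(self.ages) != sorted(set(self.ages)):
            raise ValueError("life table ages must be strictly increasing")
        for q in (*self.q_male, *self.q_female):
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"life table q out of [0,1]: {q}")
        return self

    def annual_q(self, age: float, male: bool) -> float:
        """Look up q at the last tabulated age <= ``age``.

        Ages beyond the table use the terminal row.
        """
        col = self.q_male if male else self.q_female
        a = int(age)
        if a <= self.ages[0]:
            return col[0]
        if a >= self.ages[-1]:
            return col[-1]
        # tables are dense single-year rows in practice; fall back to scan
        idx = a - self.ages[0] if self.ages == tuple(
            range(self.ages[0], self.ages[-1] + 1)) else max(
            i for i, t in enumerate(self.ages) if t <= a)
        return col[idx]


class CaseFatality(StrictModel):
    mi: float = Field(ge=0.0, le=1.0)
    unstable_angina: float = Field(ge=0.0, le=1.0)
    stroke: float = Field(ge=0.0, le=1.0)
    tia: float = Field(ge=0.0, le=1.0)
    knee_replacement: float = Field(ge=0.0, le=1.0)


class PostEventHazardRatios(StrictModel):
    post_acs: float = Field(gt=0.0)
    post_stroke: float = Field(gt=0.0)
    t2d: float = Field(gt=0.0)


class MortalityModel(StrictModel):
    """Background mortality net of modelled diseases, BMI-adjusted.

    All-cause q is reduced by the fraction of deaths attributable to the
    modelled complications, then multiplied on the rate scale by a hazard
    ratio per BMI unit above the reference.
    """

    life_table: LifeTable
    disease_specific_fraction: float = Field(ge=0.0, lt=1.0)
    bmi_hazard_ratio_per_unit: float = Field(gt=0.0)
    bmi_reference: float = Field(gt=10.0)
    case_fatality: CaseFatality
    post_event_hazard_ratios: PostEventHazardRatios


class UtilityCoefficients(StrictModel):
    intercept: float
    bmi: float
    age: float
    male: float
    coronary_artery_disease: float
    prediabetes: float
    hypertension: float
    smoking: float


class StateDisutilities(StrictModel):
    sleep_apnea: float = Field(ge=0.0)
    pre_t2d: float = Field(ge=0.0)
    t2d: float = Field(ge=0.0)
    post_acs: float = Field(ge=0.0)
    post_stroke: float = Field(ge=0.0)
    cancer: float = Field(ge=0.0)


class EventDisutilities(StrictModel):
    mi: float = Field(ge=0.0)
    unstable_angina: float = Field(ge=0.0)
    stroke: float = Field(ge=0.0)
    tia: float = Field(ge=0.0)
    knee_replacement: float = Field(ge=0.0)
    severe_gi: float = Field(ge=0.0)
    hypoglycemia: float = Field(ge=0.0)


class UtilityModel(StrictModel):
    """Regression-based baseline utility plus additive disutilities.

    Baseline (complication-free) utility is a linear function of BMI,
    age, sex and baseline comorbidity flags, clipped to [floor, 1].
    Health-state and one-off event disutilities are applied subtractively.
    """

    baseline_coefficients: UtilityCoefficients
    state_disutilities: StateDisutilities
    event_disutilities: EventDisutilities
    floor: float = Field(ge=-1.0, le=1.0, default=0.0)


class MonitoringVisit(StrictModel):
    per_year: float = Field(ge=0.0)
    unit_cost: float = Field(ge=0.0)


class StateCosts(StrictModel):
    sleep_apnea: float = Field(ge=0.0)
    pre_t2d: float = Field(ge=0.0)
    t2d: float = Field(ge=0.0)
    post_acs: float = Field(ge=0.0)
    post_stroke: float = Field(ge=0.0)
    cancer: float = Field(ge=0.0)


class EventCosts(StrictModel):
    mi: float = Field(ge=0.0)
    unstable_angina: float = Field(ge=0.0)
    stroke: float = Field(ge=0.0)
    tia: float = Field(ge=0.0)
    knee_replacement: float = Field(ge=0.0)


class AdverseEventCosts(StrictModel):
    severe_gi: float = Field(ge=0.0)
    hypoglycemia: float = Field(ge=0.0)


class CostTable(StrictModel):
    """Unit costs; the lifestyle comparator itself costs the payer nothing."""

    drug_annual_cost: float = Field(ge=0.0)
    monitoring_visits: dict[str, MonitoringVisit]
    bp_treatment_annual_cost: float = Field(ge=0.0)
    t2d_pharmacy_annual_cost: float = Field(ge=0.0)
    state_annual_costs: StateCosts
    event_costs: EventCosts
    adverse_event_costs: AdverseEventCosts

    def monitoring_annual_cost(self) -> float:
        return sum(v.per_year * v.unit_cost
                   for v in self.monitoring_visits.values())


# --- risk-equation tables (consumed by obesim.risk_engine) -----------------

#: Covariates a risk-equation predictor may reference.
PREDICTOR_SOURCES = (
    "bmi", "sbp", "total_cholesterol", "hdl", "tc_hdl_ratio",
    "prediabetes_fraction", "t2d_fraction", "age", "male",
)


class Predictor(StrictModel):
    source: Literal[
        "bmi", "sbp", "total_cholesterol", "hdl", "tc_hdl_ratio",
        "prediabetes_fraction", "t2d_fraction", "age", "male",
    ]
    transform: Literal["identity", "log"] = "identity"
    center: float = 0.0
    coefficient: float


class BaselineRateTable(StrictModel):
    """Annual baseline event rates by age band and sex."""

    age_band_lower: tuple[float, ...]
    rate_male: tuple[float, ...]
    rate_female: tuple[float, ...]

    @model_validator(mode="after")
    def _consistent(self) -> "BaselineRateTable":
        n = len(self.age_band_lower)
        if len(self.rate_male) != n or len(self.rate_female) != n:
            raise ValueError("rate table columns must have equal length")
        if list(self.age_band_lower) != sorted(self.age_band_lower):
            raise ValueError("age bands must be increasing")
        for r in (*self.rate_male, *self.rate_female):
            if r < 0.0:
                raise ValueError("baseline rates must be >= 0")
        return self

    def rate(self, age: float, male: bool) -> float:
        col = self.rate_male if male else self.rate_female
        idx = 0
        for i, lo in enumerate(self.age_band_lower):
            if age >= lo:
                idx = i
        return col[idx]


class RiskEquation(StrictModel):
    """A coefficient-table risk equation with one of four link functions.

    The published cardiovascular/diabetes scores this mirrors share this
    shape: a linear predictor over transformed, centred covariates mapped
    to an annual probability through a link.
    """

    name: str
    outcome: str
    link: Literal[
        "proportional_hazards_on_baseline_survival",
        "log_rate_linear",
        "logistic_prevalence",
        "rate_times_relative_risk",
    ]
    predictors: tuple[Predictor, ...] = ()
    intercept: float = 0.0
    baseline_survival: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    baseline_rate: Optional[float] = Field(default=None, ge=0.0)
    baseline_rate_table: Optional[BaselineRateTable] = None

    @model_validator(mode="after")
    def _link_requirements(self) -> "RiskEquation":
        if self.link == "proportional_hazards_on_baseline_survival":
            if self.baseline_survival is None:
                raise ValueError(
                    f"{self.name}: proportional-hazards link requires "
                    "baseline_survival")
        if self.link == "rate_times_relative_risk":
            if self.baseline_rate is None and self.baseline_rate_table is None:
                raise ValueError(
                    f"{self.name}: rate link requires baseline_rate or "
                    "baseline_rate_table")
        return self


class CancerRiskSpec(StrictModel):
    """Baseline cancer incidence by age/sex scaled by a BMI hazard ratio."""

    baseline_incidence: BaselineRateTable
    hr_per_5_bmi: float = Field(gt=0.0)
    bmi_reference: float = Field(gt=10.0)
    menopause_gated: bool = False
    female_only: bool = False


class CVEventSplit(StrictModel):
    """Composition of a composite cardiovascular event probability."""

    mi: float = Field(ge=0.0, le=1.0)
    unstable_angina: float = Field(ge=0.0, le=1.0)
    stroke: float = Field(ge=0.0, le=1.0)
    tia: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "CVEventSplit":
        total = self.mi + self.unstable_angina + self.stroke + self.tia
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"CV event split must sum to 1, got {total}")
        return self


class RiskEquationSet(StrictModel):
    cv_first: RiskEquation
    cv_recurrent: RiskEquation
    t2d: RiskEquation
    sleep_apnea: RiskEquation
    knee_replacement: RiskEquation
    cv_event_split: CVEventSplit
    cancers: dict[str, CancerRiskSpec]


class ArmLabels(StrictModel):
    treatment: str = "pharmacotherapy"
    comparator: str = "diet_and_exercise"


class ParameterSet(StrictModel):
    """The complete model input bundle; the unit of scenario perturbation."""

    schema_version: int = SCHEMA_VERSION
    arms: ArmLabels = ArmLabels()
    settings: EconomicSettings
    cohort: CohortProfile
    treatment_effects: TreatmentEffectSchedule
    comparator_effects: TreatmentEffectSchedule
    waning: WaningSpec
    catch_up: CatchUpSpec
    natural_progression: NaturalProgression
    bariatric: BariatricSpec
    mortality: MortalityModel
    utility: UtilityModel
    costs: CostTable
    risk_equations: RiskEquationSet
    #: when False the treated arm keeps all patients on full-sample efficacy
    #: (no non-responder switch to the comparator path)
    stopping_rule: bool = True

    @model_validator(mode="after")
    def _durations_within_horizon(self) -> "ParameterSet":
        for sched in (self.treatment_effects, self.comparator_effects):
            if sched.treatment_duration_years > self.settings.horizon_years:
                raise ValueError(
                    "treatment_duration_years exceeds the model horizon")
        return self


# --- I/O --------------------------------------------------------------------

def _check_finite(obj: Any, path: str = "") -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{path}.{k}" if path else str(k))
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{path}[{i}]")
    elif isinstance(obj, float) and not math.isfinite(obj):
        raise ValueError(f"non-finite value at {path}: {obj}")


def parameter_set_from_dict(data: dict[str, Any]) -> ParameterSet:
    _check_finite(data)
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema_version {version}; expected {SCHEMA_VERSION}")
    return ParameterSet.model_validate(data)


def parameter_set_to_dict(params: ParameterSet) -> dict[str, Any]:
    return params.model_dump(mode="json")


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Read and validate a parameter-set YAML file."""
    with open(path, "r") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return parameter_set_from_dict(data)


def save_parameter_set(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set so that loading it reproduces it exactly."""
    data = parameter_set_to_dict(params)
    _check_finite(data)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True, default_flow_style=False)


def deep_merge(base: dict, overlay: dict) -> dict:
    """Recursively merge ``overlay`` onto ``base`` (lists replaced whole)."""
    out = copy.deepcopy(base)
    for key, val in overlay.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def apply_overlay(params: ParameterSet, overlay: dict) -> ParameterSet:
    """Return a new validated ParameterSet with the overlay merged in.

    Scenario analyses are expressed as small overlay fragments on the
    base case; the merge touches only the listed fields.
    """
    merged = deep_merge(parameter_set_to_dict(params), overlay)
    return parameter_set_from_dict(merged)


def load_overlay(path: str | Path) -> dict:
    with open(path, "r") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: overlay must be a mapping")
    return data


def get_by_path(params: ParameterSet, dotted: str) -> Any:
    """Fetch a value by dotted path, e.g. ``costs.drug_annual_cost``."""
    obj: Any = params
    for part in dotted.split("."):
        if isinstance(obj, BaseModel):
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            obj = obj[part]
        elif isinstance(obj, (list, tuple)):
            obj = obj[int(part)]
        else:
            raise KeyError(f"cannot descend into {type(obj)} at {part!r}")
    return obj


def set_by_path(params: ParameterSet, dotted: str, value: Any) -> ParameterSet:
    """Return a new ParameterSet with one dotted-path field replaced."""
    data = parameter_set_to_dict(params)
    parts = dotted.split(".")
    node = data
    for part in parts[:-1]:
        if part not in node:
            raise KeyError(f"unknown parameter path {dotted!r} at {part!r}")
        node = node[part]
    if parts[-1] not in node:
        raise KeyError(f"unknown parameter path {dotted!r}")
    node[parts[-1]] = value
    return parameter_set_from_dict(data)
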