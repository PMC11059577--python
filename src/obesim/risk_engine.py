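"""Coefficient-table risk equations mapping risk factors to event risks.

The published scores wired into obesity models of this type (QRISK3-like
cardiovascular scores, QDiabetes-like diabetes incidence, Framingham-style
recurrent coronary risk, logistic sleep-apnea prevalence, registry-based
knee-replacement and cancer incidence) share a common shape: a linear
predictor over transformed, centred covariates mapped through a link to
an annual probability.  Equations are data, not code — coefficient tables
live in the parameter set and are evaluated generically here.
"""

from __future__ import annotations

import math

import numpy as np

from obesim.parameters_io import (
    CancerRiskSpec,
    Predictor,
    RiskEquation,
    RiskFactorState,
)


def rate_to_probability(rate: float, dt: float) -> float:
    """Convert a constant event rate (events/year) to a probability."""
    if rate < 0.0:
        raise ValueError("rate must be >= 0")
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    return 1.0 - math.exp(-rate * dt)


def probability_to_rate(p: float) -> float:
    if not 0.0 <= p < 1.0:
        raise ValueError("probability must be in [0, 1)")
    return -math.log1p(-p)


def probability_rescale(p_annual: float, dt: float) -> float:
    """Rescale an annual probability to a cycle length of ``dt`` years."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    return 1.0 - (1.0 - p_annual) ** dt


def _covariates(state: RiskFactorState, age: float,
                male: float) -> dict[str, float]:
    return {
        "bmi": state.bmi,
        "sbp": state.sbp,
        "total_cholesterol": state.total_cholesterol,
        "hdl": state.hdl,
        "tc_hdl_ratio": state.total_cholesterol / state.hdl,
        "prediabetes_fraction": state.glycemic_mix.prediabetes,
        "t2d_fraction": state.glycemic_mix.t2d,
        "age": age,
        "male": male,
    }


def _linear_predictor(predictors: tuple[Predictor, ...],
                      cov: dict[str, float]) -> float:
    lp = 0.0
    for p in predictors:
        if p.source not in cov:
            raise KeyError(f"predictor source {p.source!r} not available")
        x = cov[p.source]
        if p.transform == "log":
            if x <= 0.0:
                raise ValueError(
                    f"log transform of non-positive {p.source}={x}")
            x = math.log(x)
        lp += p.coefficient * (x - p.center)
    return lp


def evaluate_annual_probability(eq: RiskEquation, state: RiskFactorState,
                                age: float, male: float) -> float:
    """Annual event probability for a cohort stratum.

    ``male`` is the 0/1 indicator of the sex stratum being evaluated
    (fractional values give the mixture expectation for symmetric links
    but strata should normally be evaluated separately).
    """
    cov = _covariates(state, age, male)
    lp = _linear_predictor(eq.predictors, cov)

    if eq.link == "proportional_hazards_on_baseline_survival":
        p = 1.0 - eq.baseline_survival ** math.exp(lp)
    elif eq.link == "log_rate_linear":
        rate = math.exp(eq.intercept + lp)
        p = rate_to_probability(rate, 1.0)
    elif eq.link == "logistic_prevalence":
        p = 1.0 / (1.0 + math.exp(-(eq.intercept + lp)))
    elif eq.link == "rate_times_relative_risk":
        if eq.baseline_rate_table is not None:
            base = eq.baseline_rate_table.rate(age, male >= 0.5)
        else:
            base = eq.baseline_rate
        rate = base * math.exp(lp)
        p = rate_to_probability(rate, 1.0)
    else:  # pragma: no cover - schema forbids
        raise ValueError(f"unknown link {eq.link!r}")
    return min(1.0, max(0.0, p))


def sleep_apnea_prevalence(state: RiskFactorState, age: float, male: float,
                           eq: RiskEquation) -> float:
    """Predicted sleep-apnea prevalence (logistic link required)."""
    if eq.link != "logistic_prevalence":
        raise ValueError("sleep-apnea equation must use the logistic link")
    return evaluate_annual_probability(eq, state, age, male)


def cancer_incidence(spec: CancerRiskSpec, state: RiskFactorState, age: float,
                     male: bool, menopause_age: float) -> float:
    """Annual cancer incidence probability for one sex stratum.

    Baseline incidence by age band is scaled by the hazard ratio per
    5 kg/m2 of BMI above the reference; menopause-gated cancers
    contribute nothing before the menopause age, and female-only cancers
    nothing in the male stratum.
    """
    if age < 0.0:
        raise ValueError("age must be >= 0")
    if spec.female_only and male:
        return 0.0
    if spec.menopause_gated and age < menopause_age:
        return 0.0
    base = spec.baseline_incidence.rate(age, male)
    hr = spec.hr_per_5_bmi ** ((state.bmi - spec.bmi_reference) / 5.0)
    return rate_to_probability(base * hr, 1.0)


def all_probabilities_valid(values) -> bool:
    arr = np.asarray(values, dtype=float)
    return bool(np.all((arr >= 0.0) & (arr <= 1.0)))
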