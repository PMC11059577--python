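"""Deterministic and probabilistic sensitivity analyses.

One-way (tornado) analysis re-runs the full model at each parameter's
low/high bound (95% CI when available, else ±25% of base).  Scenario
analysis applies named overlay fragments to the base parameter set.
Probabilistic analysis draws parameters from per-parameter distributions
(beta for probabilities/utilities, gamma for costs, normal for effect
sizes), runs the full model per draw, and summarises the joint
(Δcost, ΔQALY) distribution as a CE plane and acceptability curve.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from obesim.economics import CEResult, run_ce_analysis
from obesim.parameters_io import (
    ParameterSet,
    StrictModel,
    apply_overlay,
    get_by_path,
    parameter_set_from_dict,
    parameter_set_to_dict,
)
from pydantic import Field


# --- one-way (tornado) ------------------------------------------------------

class OwsaEntry(StrictModel):
    path: str
    low: float
    high: float
    label: Optional[str] = None


class OwsaSpec(StrictModel):
    entries: tuple[OwsaEntry, ...]


def default_owsa_spec(params: ParameterSet) -> OwsaSpec:
    """±25% bounds around base for key drivers, plus the benefit-discount
    variation (0% and 6%) conventionally shown first in tornado plots."""
    def pm25(path: str) -> OwsaEntry:
        base = float(get_by_path(params, path))
        lo, hi = sorted((0.75 * base, 1.25 * base))
        return OwsaEntry(path=path, low=lo, high=hi)

    entries = [
        OwsaEntry(path="settings.discount_rate_effects", low=0.0, high=0.06),
        pm25("costs.drug_annual_cost"),
        pm25("utility.baseline_coefficients.bmi"),
        pm25("costs.t2d_pharmacy_annual_cost"),
        pm25("costs.state_annual_costs.t2d"),
        pm25("mortality.disease_specific_fraction"),
        pm25("utility.state_disutilities.t2d"),
        pm25("risk_equations.cancers.endometrial_postmenopausal."
             "baseline_incidence.rate_female.3"),
    ]
    # drop entries whose path cannot round-trip (e.g. list indices)
    ok = []
    for e in entries:
        try:
            get_by_path(params, e.path)
        except Exception:
            continue
        ok.append(e)
    return OwsaSpec(entries=tuple(ok))


def _set_path_value(params: ParameterSet, path: str, value) -> ParameterSet:
    data = parameter_set_to_dict(params)
    node = data
    parts = path.split(".")
    for part in parts[:-1]:
        node = node[int(part)] if isinstance(node, list) else node[part]
    last = parts[-1]
    if isinstance(node, list):
        node[int(last)] = value
    else:
        if last not in node:
            raise KeyError(f"unknown parameter path {path!r}")
        node[last] = value
    return parameter_set_from_dict(data)


def run_owsa(base: ParameterSet, spec: OwsaSpec) -> pd.DataFrame:
    """Tornado table: ICER at each bound, sorted by bar width descending.

    Bounds that produce an undefined ICER are flagged, not dropped.
    """
    base_result = run_ce_analysis(base)
    rows = []
    for entry in spec.entries:
        base_val = float(get_by_path(base, entry.path))
        if not (entry.low <= base_val + 1e-9 and
                base_val - 1e-9 <= entry.high):
            raise ValueError(
                f"{entry.path}: base value {base_val} outside "
                f"[{entry.low}, {entry.high}]")
        icers = {}
        nmbs = {}
        for bound, val in (("low", entry.low), ("high", entry.high)):
            res = run_ce_analysis(_set_path_value(base, entry.path, val))
            icers[bound] = res.icer_per_qaly
            nmbs[bound] = res.nmb
        defined = all(v is not None for v in icers.values())
        rows.append({
            "parameter": entry.label or entry.path,
            "low": entry.low, "high": entry.high, "base": base_val,
            "icer_low": icers["low"], "icer_high": icers["high"],
            "nmb_low": nmbs["low"], "nmb_high": nmbs["high"],
            "icer_defined": defined,
            "width": (abs(icers["high"] - icers["low"]) if defined
                      else float("nan")),
        })
    df = pd.DataFrame(rows)
    df["base_icer"] = base_result.icer_per_qaly
    return df.sort_values("width", ascending=False,
                          na_position="last").reset_index(drop=True)


# --- scenarios --------------------------------------------------------------

# Trial-product (on-treatment) effect estimates, synthetic analogues of
# the intention-to-treat values, derived with the same responder mixture.
_TRIAL_PRODUCT_EFFECTS = {
    "treatment_effects": {
        "week28_full": {"relative_weight_change": -0.110},
        "week68_full": {"relative_weight_change": -0.160},
        "week28_responder": {"relative_weight_change": -0.12850},
        "week68_responder": {"relative_weight_change": -0.18648},
    }
}

_ALT_UTILITY = {
    "utility": {
        "baseline_coefficients": {
            "intercept": 1.010, "bmi": -0.0038, "age": -0.0014,
            "male": 0.012, "coronary_artery_disease": -0.055,
            "prediabetes": -0.010, "hypertension": -0.013,
            "smoking": -0.018}}
}

_ALT_CV_EQUATIONS = {
    "risk_equations": {
        "cv_first": {"baseline_survival": 0.988},
        "cv_recurrent": {"intercept": -3.0},
    }
}

SCENARIO_PRESETS: dict[str, dict] = {
    "treatment_policy_no_stopping_rule": {"stopping_rule": False},
    "trial_product_with_stopping_rule": copy.deepcopy(
        _TRIAL_PRODUCT_EFFECTS),
    "trial_product_no_stopping_rule": {
        **copy.deepcopy(_TRIAL_PRODUCT_EFFECTS), "stopping_rule": False},
    "treatment_duration_3_years": {
        "treatment_effects": {"treatment_duration_years": 3}},
    "treatment_duration_6_years": {
        "treatment_effects": {"treatment_duration_years": 6}},
    "slower_return_rate_33_67_100": {
        "catch_up": {"cumulative_fractions": [0.33, 0.67, 1.0]}},
    "literature_bmi_utility": copy.deepcopy(_ALT_UTILITY),
    "alternative_cv_risk_equations": copy.deepcopy(_ALT_CV_EQUATIONS),
    "disease_mortality_only": {
        "mortality": {"bmi_hazard_ratio_per_unit": 1.0,
                      "disease_specific_fraction": 0.0}},
}


def run_scenarios(base: ParameterSet,
                  presets: dict[str, dict] | None = None) -> pd.DataFrame:
    """Scenario table: per-arm totals, ICER, and % change vs base ICER."""
    presets = SCENARIO_PRESETS if presets is None else presets
    base_result = run_ce_analysis(base)
    rows = [_scenario_row("base_case", base_result, base_result)]
    for name, overlay in presets.items():
        try:
            scen = apply_overlay(base, overlay)
        except Exception as exc:
            raise ValueError(f"invalid overlay for scenario {name!r}: {exc}"
                             ) from exc
        rows.append(_scenario_row(name, run_ce_analysis(scen), base_result))
    return pd.DataFrame(rows)


def _scenario_row(name: str, res: CEResult, base: CEResult) -> dict:
    pct = float("nan")
    if res.icer_per_qaly is not None and base.icer_per_qaly:
        pct = 100.0 * (res.icer_per_qaly / base.icer_per_qaly - 1.0)
    return {"scenario": name,
            "cost_treatment": res.treatment.total_cost,
            "cost_comparator": res.comparator.total_cost,
            "qalys_treatment": res.treatment.qalys,
            "qalys_comparator": res.comparator.qalys,
            "delta_cost": res.delta_cost, "delta_qalys": res.delta_qalys,
            "icer": res.icer_per_qaly, "classification": res.classification,
            "pct_change_vs_base": pct}


# --- probabilistic ----------------------------------------------------------

class PSAEntry(StrictModel):
    path: str
    family: Literal["beta", "gamma", "normal"]
    #: standard deviation; if None, ``rel_sd`` × |base| is used
    sd: Optional[float] = Field(default=None, ge=0.0)
    rel_sd: float = Field(default=0.10, ge=0.0)


class PSASpec(StrictModel):
    entries: tuple[PSAEntry, ...]
    iterations: int = Field(default=1000, ge=1)
    seed: int = 0


def default_psa_spec(params: ParameterSet, iterations: int = 1000,
                     seed: int = 0) -> PSASpec:
    entries = (
        PSAEntry(path="costs.drug_annual_cost", family="gamma"),
        PSAEntry(path="costs.t2d_pharmacy_annual_cost", family="gamma"),
        PSAEntry(path="costs.state_annual_costs.t2d", family="gamma"),
        PSAEntry(path="costs.state_annual_costs.post_acs", family="gamma"),
        PSAEntry(path="costs.state_annual_costs.sleep_apnea",
                 family="gamma"),
        PSAEntry(path="costs.event_costs.mi", family="gamma"),
        PSAEntry(path="utility.state_disutilities.t2d", family="beta",
                 rel_sd=0.10),
        PSAEntry(path="utility.state_disutilities.post_stroke",
                 family="beta", rel_sd=0.10),
        PSAEntry(path="treatment_effects.responder_proportion",
                 family="beta", sd=0.015),
        PSAEntry(path="treatment_effects.week68_full.relative_weight_change",
                 family="normal", sd=0.008),
        PSAEntry(path="treatment_effects.week68_full.sbp_change",
                 family="normal", sd=0.5),
        PSAEntry(path="comparator_effects.week68_full."
                      "relative_weight_change", family="normal", sd=0.004),
        PSAEntry(path="mortality.disease_specific_fraction", family="beta",
                 rel_sd=0.10),
    )
    return PSASpec(entries=entries, iterations=iterations, seed=seed)


def _draw(entry: PSAEntry, base: float, rng: np.random.Generator) -> float:
    sd = entry.sd if entry.sd is not None else entry.rel_sd * abs(base)
    if sd == 0.0:
        return base
    if entry.family == "normal":
        return float(rng.normal(base, sd))
    if entry.family == "gamma":
        if base <= 0.0:
            return base
        shape = (base / sd) ** 2
        scale = sd * sd / base
        return float(rng.gamma(shape, scale))
    # beta by method of moments; requires mean in (0, 1)
    if not 0.0 < base < 1.0:
        return base
    var = sd * sd
    max_var = base * (1.0 - base)
    var = min(var, 0.99 * max_var)
    nu = base * (1.0 - base) / var - 1.0
    return float(rng.beta(base * nu, (1.0 - base) * nu))


@dataclass
class PSASample:
    draw: int
    delta_cost: float
    delta_qalys: float


@dataclass
class PSAResult:
    samples: list[PSASample]
    mean_delta_cost: float
    mean_delta_qalys: float
    ui95_delta_cost: tuple[float, float]
    ui95_delta_qalys: tuple[float, float]
    rejected_draws: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"draw": s.draw, "delta_cost": s.delta_cost,
              "delta_qalys": s.delta_qalys} for s in self.samples])


def run_psa(base: ParameterSet, spec: PSASpec) -> PSAResult:
    """Monte-Carlo PSA: per-draw full model evaluation, seeded.

    Draws that fail parameter validation (e.g. a normal tail outside a
    field's validity range) are rejected and redrawn; the count is
    reported on the result.
    """
    rng = np.random.default_rng(spec.seed)
    base_vals = {e.path: float(get_by_path(base, e.path))
                 for e in spec.entries}
    base_data = parameter_set_to_dict(base)

    def _set_in_dict(data: dict, path: str, value: float) -> None:
        node = data
        parts = path.split(".")
        for part in parts[:-1]:
            node = node[int(part)] if isinstance(node, list) else node[part]
        if isinstance(node, list):
            node[int(parts[-1])] = value
        else:
            node[parts[-1]] = value

    samples: list[PSASample] = []
    rejected = 0
    for i in range(spec.iterations):
        for _attempt in range(100):
            try:
                data = copy.deepcopy(base_data)
                for e in spec.entries:
                    _set_in_dict(data, e.path,
                                 _draw(e, base_vals[e.path], rng))
                draw_params = parameter_set_from_dict(data)
                break
            except (ValueError, KeyError):
                rejected += 1
        else:
            raise RuntimeError("could not obtain a valid PSA draw")
        res = run_ce_analysis(draw_params)
        samples.append(PSASample(draw=i, delta_cost=res.delta_cost,
                                 delta_qalys=res.delta_qalys))
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qalys for s in samples])
    return PSAResult(
        samples=samples,
        mean_delta_cost=float(dc.mean()),
        mean_delta_qalys=float(dq.mean()),
        ui95_delta_cost=(float(np.percentile(dc, 2.5)),
                         float(np.percentile(dc, 97.5))),
        ui95_delta_qalys=(float(np.percentile(dq, 2.5)),
                          float(np.percentile(dq, 97.5))),
        rejected_draws=rejected)


def ceac(samples: list[PSASample], wtp_grid) -> pd.DataFrame:
    """Probability of positive net monetary benefit across WTP values."""
    if not samples:
        raise ValueError("CEAC requires at least one sample")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qalys for s in samples])
    rows = []
    for lam in wtp_grid:
        prob = float(np.mean(lam * dq - dc > 0.0))
        rows.append({"wtp": float(lam), "probability_cost_effective": prob})
    return pd.DataFrame(rows)
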