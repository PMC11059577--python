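# Methods

This note records the modelling assumptions, numerical choices and
design decisions behind `obesim`, in the spirit of a model technical
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structure

An expected-value (cohort) Markov state-transition model with states

> no comorbidity → sleep apnea → pre-T2D → T2D → cancer → post-ACS →
> post-stroke → dead

ordered by precedence for costing and utility (dead > post-stroke >
post-ACS > cancer > T2D > pre-T2D > sleep apnea > none). Transient
events (MI, unstable angina, stroke, TIA, knee replacement, bariatric
surgery) carry one-off costs and disutilities and, for cardiovascular
events, move survivors into the post-ACS/post-stroke states. The first
model year runs four quarterly cycles (to resolve the week-28 stopping
rule); subsequent cycles are annual with half-cycle correction
implemented as trapezoidal averaging of start- and end-of-cycle
occupancy. Quarterly cycles are short enough that end-of-cycle
occupancy is used directly.

Within each cycle the order of operations is fixed: (1) background +
disease mortality, (2) acute events with case fatality, (3) chronic
transitions (T2D and cancer incidence, then prevalence rebalancing),
(4) bariatric uptake. The literature this model class comes from does
not specify an order; mortality-first is the conservative convention.
Each step is a row-stochastic linear map, so the cycle's total update
is recorded as a single transition matrix per sex stratum. That makes
the cohort arithmetic directly checkable against an individual-level
microsimulation sampling the same matrices (`generate_microsim_oracle`),
which is how the engine is validated.

Sex is handled as two strata (male/female sub-cohorts sharing the
cohort-level risk-factor trajectory) rather than an averaged covariate;
menopause gating of the female cancers and sex-specific life tables are
otherwise ill-defined.

### Prevalence-driven states

Sleep apnea is a prevalence condition, not an incidence process: each
cycle the sleep-apnea share of the {none, sleep apnea} pool is
rebalanced to the logistic-equation prediction at the current BMI.
Similarly the prediabetes/NGT split inside the low-precedence pool
tracks the trajectory's glycemic mix, which is how the temporary
prediabetes reversal (cycle 2, maintained by waning, unwound by
catch-up) propagates into state occupancy. T2D and cancer are absorbing
chronic states fed by incidence equations.

## Trajectories

Trial effects are "value reached by end of cycle": half the week-28
full-sample effect at cycle 1, the week-28 level at cycle 2, the
responder week-68 level at cycle 4, linear in between. The responder
subset's effects are derived from the full-sample and comparator values
through the mixture identity `full = p·responder + (1−p)·comparator`,
so the treated arm's merged cycle-4 state reproduces the
intention-to-treat week-68 change exactly while non-responders (the
stopping rule, from cycle 3) follow the comparator path.

Year 2 applies the early-responder waning ratio to the week-68 effect;
from year 3 the full-analysis-set ratio compounds yearly while on
treatment. Total cholesterol and HDL are held constant at their week-68
changes (no later trial assessment exists). After treatment stops, the
catch-up schedule closes the gap between the value at stop and the
reference (baseline by default; the D&E trajectory is a config option).
The base-case schedule is full return in one year (`[1.0]`); the slower
`[0.33, 0.67, 1.0]` return is a scenario preset. Natural weight gain
(sex-mixed 0.463 kg/year, converted to BMI units via the cohort mean
height, 1.66 m) accrues from catch-up completion until age 68. BMI is
floored at 18.5 kg/m² to keep risk-equation inputs physiological.

## Risk equations

Equations are data, not code: a predictor list (source covariate,
identity/log transform, centring offset, coefficient) plus one of four
links —

- `proportional_hazards_on_baseline_survival`: p = 1 − S₀^exp(lp)
- `log_rate_linear`: rate = exp(intercept + lp)
- `logistic_prevalence`: p = logit⁻¹(intercept + lp)
- `rate_times_relative_risk`: rate = baseline(age, sex) · exp(lp)

Annual probabilities are rescaled to cycle length as
1 − (1 − p)^dt; rates convert via 1 − exp(−r·dt). Cancer incidence uses
baseline rates by age band and sex scaled by HR^((BMI − ref)/5), with
post-menopausal breast and endometrial cancers gated at the menopause
age (48) and restricted to the female stratum. First cardiovascular
events use one composite equation split into MI/UA/stroke/TIA by fixed
fractions; recurrent events use a separate equation for the
post-ACS/post-stroke sub-cohorts (TIA and unstable angina feed the
post-stroke and post-ACS history states respectively).

## Mortality

Background mortality is all-cause q net of the disease-specific
fraction (deaths attributable to modelled complications), multiplied on
the rate scale by HR_BMI^(BMI − 25). Post-event hazard ratios (post-ACS,
post-stroke, T2D) multiply the background rate of those states. This
multiplicative composition can double-count some mortality; the
"disease-mortality only" scenario preset (HR = 1, no deduction)
brackets the assumption from the other side.

## Economics

Baseline utility is the linear BMI/age/sex/comorbidity regression
clipped to [floor, 1] (floor 0.3); state disutilities subtract from it
per occupancy, event disutilities subtract once in the event cycle.
Adverse events (severe GI, non-severe hypoglycemia) accrue per
patient-year on drug, treated arm only, during treatment. Discounting
uses (1 + r)^(−t) with t at the cycle midpoint for annual cycles and
the cycle start for quarterly ones, matching the half-cycle-corrected
accrual. Costs and effects carry separate rate fields (both 4 % by
default) so the benefit-rate tornado bar (0 %–6 %) is expressible.
ICERs are computed from unrounded accumulators; dominance suppresses
the ratio rather than reporting a negative number. Cost categories
(pharmacotherapy; monitoring + D&E; blood-pressure treatment; T2D
pharmacy; complication states; complication events) sum to the total
by construction, and the suite asserts the closure.

## Sensitivity analyses

- **One-way**: each parameter run at low/high (±25 % of base where no
  interval is available; the benefit discount rate at 0 %/6 %), all
  else at base; bars sorted by ICER range. An NMB-range metric is
  available where ΔQALY is near zero.
- **Scenarios**: nine shipped overlay presets (no stopping rule,
  trial-product effect estimates with/without stopping rule, 3- and
  6-year treatment duration, slower catch-up, literature BMI-utility,
  alternative CV equations, disease-mortality only). Overlays are deep
  merges that touch only their listed fields (asserted by deep diff).
- **PSA**: per-parameter distributions — beta for probabilities and
  disutilities, gamma for costs, normal for effect changes — matched to
  the base value by method of moments (default spread 10 % of base
  unless an absolute sd is given), independently drawn; no correlation
  structure is imposed. Draws failing schema validation are rejected
  and redrawn with a logged count. 95 % uncertainty intervals are
  equal-tailed percentiles. The CEAC reports, per willingness-to-pay λ,
  the fraction of draws with λ·ΔQALY − ΔC > 0.

## Synthetic data

The generator emulates the *statistical shape* of the trial-derived
inputs this model class consumes: relative weight change −14.9 %
(treated) vs −2.4 % (comparator) at week 68, 83.7 % responders at week
28, SBP/lipid improvements of trial-like magnitude, a 48-year-old
cohort at BMI 37.5 with 45 % prediabetes, monitoring visits
4.5 + 3.61 + 0.16 per year, discounting at 4 % over 40 years against a
20,000 EUR/QALY threshold, and bariatric-surgery weight loss of 23 %
in year 1 maintained at 18 % long-run. The life table is a two-
parameter Gompertz law q(a) = α·e^{β(a−40)} (α = 8·10⁻⁴ male, 5·10⁻⁴
female; β = 0.095), closed at q(110) = 1 — monotone and representative
of a Southern-European adult population without copying any national
table.

What the fixture does **not** emulate: real cost microdata, licensed
risk-equation coefficients, utility regressions from trial SF-36 data,
or patient-level heterogeneity beyond the responder split. Passing
tests therefore demonstrate that the machinery is correct and
internally consistent — conservation, absorption, monotonicity, oracle
agreement, reporting arithmetic — not that any particular published
ICER is reproduced. Synthetic costs are order-of-magnitude plausible
and scaled so the base run lands in the northeast quadrant of the CE
plane (more costly, more effective), which is the informative regime
for ICER/CEAC machinery; they are deliberately not tuned further.

## Problem sizes and numerics

- Horizon 40 years → 43 cycles; a full two-arm evaluation runs in tens
  of milliseconds, so scenario tables and 1000-draw PSAs are cheap.
- The engine validates every cycle's transition matrix (row sums within
  10⁻⁸, no negative entries) and aborts on violation.
- The microsimulation oracle checks use 2·10⁵ individuals on a
  three-state instance (3 binomial standard errors per cycle) and
  2·10⁴ individuals on the full model (looser spot check); the
  PSA-convergence check uses 300 mean-centred draws against a
  3-standard-error band.
- Tie-breaks: recurrent coronary events do not demote the post-stroke
  sub-cohort; a terminal life-table row covers ages beyond the table;
  q = 1 rows map to a large finite hazard before cycle-length rescaling.

## Known limitations

- Single-state comorbidity hierarchy: a member occupies one costed
  state; event risks use history flags but multimorbidity costs are
  not additive across states.
- No T2D microvascular sub-progression (single T2D cost/utility), no
  cancer survivorship tunnels, no re-treatment after catch-up, no
  societal-perspective costs.
- The BMI-dependent background mortality and post-event hazard ratios
  compose multiplicatively; the true interaction is unidentified from
  the sources this model class draws on.
- Currency values are plain decimals tagged with `currency_year`
  metadata; no inflation adjustment or conversion is performed.
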