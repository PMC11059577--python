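# obesim

A Markov state-transition cohort model for the health economics of
chronic weight management. `obesim` converts trial-derived changes in
surrogate risk factors — BMI, systolic blood pressure (SBP), lipids and
glycemic status — into the incidence of obesity-related complications
(type 2 diabetes, myocardial infarction, unstable angina, stroke, TIA,
sleep apnea, colon and post-menopausal breast/endometrial cancers, knee
replacement), and reports discounted costs, QALYs, life-years,
incremental cost-effectiveness ratios (ICERs) and net monetary benefit
for a pharmacotherapy arm versus a diet-and-exercise (D&E) comparator,
with one-way, scenario and probabilistic sensitivity analyses.

It is written for health-economics and outcomes researchers who need a
*tested, scriptable* implementation of this model class rather than a
spreadsheet: every input is a validated, versioned YAML parameter set;
every analysis is a pure function of that parameter set; and the cohort
arithmetic is verified against an individual-level microsimulation.

## The model

The cohort (mean age 48, BMI ≥ 30 kg/m², ≥ 1 weight-related
comorbidity) is tracked through mutually exclusive health states over
quarterly cycles in year 1 and annual cycles thereafter (half-cycle
corrected), for a default horizon of 40 years.

**Risk-factor trajectories.** Trial effects enter as change-from-
baseline at weeks 28 and 68. The full-sample effect applies in cycle 2;
the responder-subset effect (patients with ≥ 5 % weight loss at week
28) applies in cycles 3–4, while the non-responder fraction (16.3 %)
stops drug under the stopping rule and inherits the comparator path.
Year-2 effects are the week-68 effect scaled by an early-responder
waning ratio; from year 3 a full-analysis-set ratio compounds while on
treatment. After treatment stops (base case: 2 years) a catch-up
schedule returns risk factors to the reference path, after which weight
rises naturally at 0.402 / 0.486 kg/year (men / women) until age 68.
Bariatric surgery is available post-treatment while cohort mean BMI
stays above the eligibility threshold.

**Risk equations.** Complication incidence is produced by pluggable
coefficient-table equations with four link functions (proportional
hazards on a baseline survival, log-linear rate, logistic prevalence,
baseline rate × relative risk), mirroring the structure of the
QRISK3 / QDiabetes / Framingham-recurrent family of published scores.
The shipped coefficient sets are synthetic: the licensed originals are
not redistributable, and the model's contribution is how the equations
are wired, not their values.

**Mortality.** A life table supplies all-cause death probabilities by
age and sex; the disease-specific fraction is subtracted and the
remainder scaled on the rate scale by a hazard ratio per BMI unit.
Acute events carry case fatality; post-ACS, post-stroke and T2D states
carry excess-mortality hazard ratios.

**Economics.** A regression gives baseline (complication-free) utility
as a function of BMI, age, sex and baseline comorbidity; state and
event disutilities are subtracted additively. Costs cover drug,
monitoring (applied to both arms; D&E itself costs the payer nothing),
blood-pressure treatment, T2D pharmacy, chronic complication states and
one-off events. Costs and effects are discounted at 4 %/year, and

> ICER = (C₁ − C₀) / (E₁ − E₀),  NMB = λ·ΔE − ΔC

with λ the willingness-to-pay threshold (default 20,000 EUR/QALY).

## Worked example

```bash
obesim run fixtures/step1_like.yaml --outdir results/
```

prints, for the shipped synthetic trial-like fixture:

```
delta cost: 2,297.27
delta QALYs: 0.0522
ICER: 43,972 per QALY
NMB at WTP 20,000: -1,252.40
```

i.e. over 40 years, pharmacotherapy adds 2,297 EUR of discounted cost
and 0.052 discounted QALYs per patient relative to D&E alone, an ICER
of ~44,000 EUR per QALY gained under the *synthetic* cost/utility
fixture (deliberately not calibrated to any published price year — the
fixture demonstrates the machinery, not a reimbursement verdict). The
output directory gains the full cost breakdown (`ce_results.tsv`),
event rates per 100 patient-years (`event_rates_per_100py.tsv`),
person-years by health state, per-cycle BMI trajectories for both arms,
per-cycle traces, and a manifest sufficient to repeat the run.

Sensitivity analyses:

```bash
obesim scenarios fixtures/step1_like.yaml --outdir results/   # 9 presets
obesim owsa fixtures/step1_like.yaml --outdir results/        # tornado
obesim psa fixtures/step1_like.yaml --seed 7 --iterations 1000 \
    --outdir results/                                         # CE plane + CEAC
```

From Python:

```python
from obesim import generate_parameter_set, SyntheticSpec
from obesim.economics import run_ce_analysis

params = generate_parameter_set(SyntheticSpec(profile="step1_like"))
result = run_ce_analysis(params)
print(result.icer_per_qaly, result.classification)
```

## Layout

| module | contents |
|---|---|
| `obesim.parameters_io` | validated parameter-set types, YAML I/O, overlays |
| `obesim.trajectories` | per-cycle risk-factor paths, stopping rule, waning, catch-up |
| `obesim.risk_engine` | coefficient-table risk equations, four link functions |
| `obesim.markov_engine` | cohort propagation, mortality, events, half-cycle correction |
| `obesim.economics` | utilities, costs, discounting, ICER/NMB |
| `obesim.sensitivity` | tornado, scenario presets, PSA, CEAC |
| `obesim.synthetic_data` | parameter-set generator, life table, microsim oracle |
| `obesim.cli` | `obesim run / owsa / scenarios / psa / generate-fixture / validate` |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
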