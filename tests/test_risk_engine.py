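"""Risk-equation links, conversions and monotonicity properties."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from obesim.parameters_io import (
    CancerRiskSpec,
    GlycemicMix,
    RiskEquation,
    RiskFactorState,
)
from obesim.risk_engine import (
    cancer_incidence,
    evaluate_annual_probability,
    probability_rescale,
    rate_to_probability,
    sleep_apnea_prevalence,
)


def make_state(bmi=35.0, sbp=125.0, tc=5.0, hdl=1.2, pre=0.4, t2d=0.0):
    return RiskFactorState(
        bmi=bmi, sbp=sbp, total_cholesterol=tc, hdl=hdl,
        glycemic_mix=GlycemicMix(ngt=1.0 - pre - t2d, prediabetes=pre,
                                 t2d=t2d))


class TestConversions:
    def test_zero_rate_zero_probability(self):
        assert rate_to_probability(0.0, 1.0) == 0.0

    def test_ln2_rate_gives_half(self):
        assert rate_to_probability(math.log(2.0), 1.0) == pytest.approx(0.5)

    def test_rescale_boundaries(self):
        assert probability_rescale(0.0, 0.25) == 0.0
        assert probability_rescale(1.0, 0.25) == 1.0

    def test_rescale_quarterly_value(self):
        assert probability_rescale(0.19, 0.25) == \
            pytest.approx(1.0 - 0.81 ** 0.25)

    @given(st.floats(0.0, 0.999))
    @settings(max_examples=100, deadline=None)
    def test_quarterly_composition_recovers_annual(self, p):
        p_q = probability_rescale(p, 0.25)
        assert 1.0 - (1.0 - p_q) ** 4 == pytest.approx(p, abs=1e-12)


class TestProportionalHazardsLink:
    def test_null_linear_predictor_gives_one_minus_s0(self):
        eq = RiskEquation(name="e", outcome="x",
                          link="proportional_hazards_on_baseline_survival",
                          baseline_survival=0.97, predictors=())
        p = evaluate_annual_probability(eq, make_state(), 48.0, 0.0)
        assert p == pytest.approx(1.0 - 0.97)

    def test_reference_covariates_give_baseline_probability(self):
        # closed form: at the centred reference point lp = 0, p = 1 - S0
        eq = RiskEquation(
            name="cv", outcome="cv",
            link="proportional_hazards_on_baseline_survival",
            baseline_survival=0.99,
            predictors=({"source": "bmi", "center": 35.0,
                         "coefficient": 0.03},
                        {"source": "age", "center": 48.0,
                         "coefficient": 0.07}))
        p = evaluate_annual_probability(eq, make_state(bmi=35.0), 48.0, 0.0)
        assert p == pytest.approx(0.01, abs=1e-12)

    def test_doubling_coefficient_increases_probability(self):
        def eq_with(coef):
            return RiskEquation(
                name="cv", outcome="cv",
                link="proportional_hazards_on_baseline_survival",
                baseline_survival=0.99,
                predictors=({"source": "bmi", "center": 30.0,
                             "coefficient": coef},))
        state = make_state(bmi=40.0)  # positive centred predictor
        p1 = evaluate_annual_probability(eq_with(0.02), state, 48.0, 0.0)
        p2 = evaluate_annual_probability(eq_with(0.04), state, 48.0, 0.0)
        assert p2 > p1

    @given(st.floats(20, 60), st.floats(90, 200), st.floats(30, 80),
           st.floats(0.5, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_probability_always_in_unit_interval(self, bmi, sbp, age, male):
        eq = RiskEquation(
            name="cv", outcome="cv",
            link="proportional_hazards_on_baseline_survival",
            baseline_survival=0.99,
            predictors=({"source": "bmi", "center": 30.0,
                         "coefficient": 0.05},
                        {"source": "sbp", "center": 130.0,
                         "coefficient": 0.02},
                        {"source": "age", "center": 48.0,
                         "coefficient": 0.08}))
        p = evaluate_annual_probability(eq, make_state(bmi=bmi, sbp=sbp),
                                        age, male)
        assert 0.0 <= p <= 1.0

    @given(st.floats(25, 45), st.floats(0.1, 14.9))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_bmi_for_positive_coefficient(self, bmi, dbmi):
        eq = RiskEquation(
            name="cv", outcome="cv",
            link="proportional_hazards_on_baseline_survival",
            baseline_survival=0.99,
            predictors=({"source": "bmi", "center": 30.0,
                         "coefficient": 0.04},))
        p_lo = evaluate_annual_probability(eq, make_state(bmi=bmi), 48.0, 0.0)
        p_hi = evaluate_annual_probability(eq, make_state(bmi=bmi + dbmi),
                                           48.0, 0.0)
        assert p_hi >= p_lo


class TestSleepApneaPrevalence:
    def _eq(self, bmi_coef=0.1):
        return RiskEquation(
            name="sa", outcome="sleep_apnea", link="logistic_prevalence",
            intercept=-1.2,
            predictors=({"source": "bmi", "center": 30.0,
                         "coefficient": bmi_coef},))

    def test_zero_bmi_coefficient_makes_prevalence_flat(self):
        eq = self._eq(bmi_coef=0.0)
        p30 = sleep_apnea_prevalence(make_state(bmi=30), 48.0, 0.0, eq)
        p45 = sleep_apnea_prevalence(make_state(bmi=45), 48.0, 0.0, eq)
        assert p30 == p45

    def test_prevalence_increases_with_bmi(self):
        eq = self._eq()
        assert sleep_apnea_prevalence(make_state(bmi=40), 48.0, 0.0, eq) > \
            sleep_apnea_prevalence(make_state(bmi=30), 48.0, 0.0, eq)

    def test_logistic_identity_at_zero(self):
        eq = RiskEquation(name="sa", outcome="sa",
                          link="logistic_prevalence", intercept=0.0,
                          predictors=())
        assert sleep_apnea_prevalence(make_state(), 48.0, 0.0, eq) == 0.5

    def test_non_logistic_link_rejected(self):
        eq = RiskEquation(name="x", outcome="x", link="log_rate_linear",
                          intercept=-3.0)
        with pytest.raises(ValueError):
            sleep_apnea_prevalence(make_state(), 48.0, 0.0, eq)


class TestCancerIncidence:
    def _spec(self, hr=1.5, gated=True):
        return CancerRiskSpec(
            baseline_incidence={"age_band_lower": [40.0, 60.0],
                                "rate_male": [0.001, 0.002],
                                "rate_female": [0.001, 0.002]},
            hr_per_5_bmi=hr, bmi_reference=25.0,
            menopause_gated=gated, female_only=True)

    def test_gated_cancer_zero_before_menopause(self):
        p = cancer_incidence(self._spec(), make_state(), 45.0, False, 48.0)
        assert p == 0.0

    def test_bmi_at_reference_gives_baseline(self):
        p = cancer_incidence(self._spec(gated=False), make_state(bmi=25.0),
                             50.0, False, 48.0)
        assert p == pytest.approx(rate_to_probability(0.001, 1.0))

    def test_hr_exponent_arithmetic(self):
        # BMI 10 above reference with HR 1.5 per 5 units: rate x 2.25
        p = cancer_incidence(self._spec(gated=False), make_state(bmi=35.0),
                             50.0, False, 48.0)
        assert p == pytest.approx(rate_to_probability(0.001 * 2.25, 1.0))

    def test_female_only_cancer_zero_in_male_stratum(self):
        p = cancer_incidence(self._spec(gated=False), make_state(), 50.0,
                             True, 48.0)
        assert p == 0.0
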