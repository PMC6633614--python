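"""Dose-response, intervention, mediation, and PIF behaviour."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from msltce.riskmodel import (
    ExposureDistribution,
    Intervention,
    PACategory,
    apply_intervention,
    categorize_pa,
    diabetes_cvd_multiplier,
    intermediate_shift,
    mediation_adjust,
    pa_relative_risk,
    pa_rr_deconfound,
    pif_truncnorm,
    relative_risk_at,
    rr_function,
)


def _dist(factor, mean, sd, nonconsumer=None):
    rows = []
    for sex in ("male", "female"):
        row = {"sex": sex, "age": 50, "mean": mean, "sd": sd}
        if nonconsumer is not None:
            row["nonconsumer"] = nonconsumer
        rows.append(row)
    return ExposureDistribution(factor, pd.DataFrame(rows))


class TestIntervention:
    def test_absolute_shift(self):
        d = _dist("salt", 8.0, 2.0)
        out = apply_intervention(d, Intervention("salt", "absolute", -1.0))
        assert out.data["mean"].tolist() == [7.0, 7.0]
        assert out.data["sd"].tolist() == [2.0, 2.0]

    def test_relative_shift(self):
        d = _dist("salt", 8.0, 2.0)
        out = apply_intervention(d, Intervention("salt", "relative", -0.10))
        assert out.data["mean"].iloc[0] == pytest.approx(7.2)

    def test_floor_at_zero(self):
        d = _dist("salt", 8.0, 2.0)
        out = apply_intervention(d, Intervention("salt", "absolute", -10.0))
        assert (out.data["mean"] == 0.0).all()

    def test_factor_mismatch(self):
        with pytest.raises(ValueError, match="salt"):
            apply_intervention(_dist("fruit", 100, 50),
                               Intervention("salt", "absolute", -1.0))


class TestIntermediateShift:
    def test_saturated_fat_to_cholesterol(self, ps):
        out = intermediate_shift({"saturated_fat": 1.0}, ps)
        assert out["cholesterol"] == pytest.approx(0.052)

    def test_salt_sodium_conversion(self, ps):
        # -1 g/day salt -> -17.1 mmol Na -> 5.80 * (-17.1/100) mmHg
        out = intermediate_shift({"salt": -1.0}, ps)
        assert out["sbp"] == pytest.approx(-0.9918)

    def test_zero_deltas(self, ps):
        out = intermediate_shift({"salt": 0.0, "pufa": 0.0}, ps)
        assert out == {"sbp": 0.0, "cholesterol": 0.0, "bmi": 0.0}

    def test_energy_to_bmi_linear(self, ps):
        out = intermediate_shift({"total_energy": -500.0}, ps, sex="male")
        assert out["bmi"] == pytest.approx(-500 * 0.010 / 1.75**2)


class TestRelativeRisk:
    def test_red_meat_at_one_unit_above_minimum(self, ps):
        rr = ps.rr("red_meat", "colorectal_cancer")
        assert relative_risk_at(114.3, rr, ps.tmin("red_meat")) == pytest.approx(1.30)

    def test_identity_at_minimum(self, ps):
        rr = ps.rr("red_meat", "colorectal_cancer")
        assert relative_risk_at(14.3, rr, ps.tmin("red_meat")) == pytest.approx(1.0)

    def test_clamped_below_minimum(self, ps):
        rr = ps.rr("red_meat", "colorectal_cancer")
        assert relative_risk_at(5.0, rr, ps.tmin("red_meat")) == pytest.approx(1.0)

    def test_negative_intake_rejected(self, ps):
        rr = ps.rr("red_meat", "colorectal_cancer")
        with pytest.raises(ValueError):
            relative_risk_at(-1.0, rr, ps.tmin("red_meat"))

    def test_protective_factor_harmful_below_minimum(self, ps):
        # fruit below its minimum-risk intake carries excess risk
        rr = ps.rr("fruit", "ihd")
        val = relative_risk_at(194.0, rr, ps.tmin("fruit"))  # 106 below tmin
        assert val == pytest.approx(1 / 0.93, rel=1e-9)

    def test_negative_unit_convention(self, ps):
        # cholesterol RR is per -1 mmol/L; above the minimum risk rises
        rr = ps.rr("cholesterol", "ihd", age=45)
        val = relative_risk_at(4.8, rr, ps.tmin("cholesterol"))
        assert val == pytest.approx(1 / 0.44, rel=1e-9)

    def test_exposure_banded_curve_continuous(self, ps):
        specs = ps.rr_entries("bmi", "diabetes")
        fn = rr_function(specs, ps.tmin("bmi").value)
        x = np.linspace(18, 40, 200)
        y = fn(x)
        assert np.all(np.isfinite(y))
        # continuity across the 25 kg/m^2 band edge
        assert abs(fn(np.array([24.999]))[0] - fn(np.array([25.001]))[0]) < 1e-3
        # steep rise above 25 (RR 2.16 per 5 units, unclamped curve)
        raw = rr_function(specs, ps.tmin("bmi").value, clamp=False)
        assert raw(np.array([30.0]))[0] == pytest.approx(
            raw(np.array([25.0]))[0] * 2.16, rel=1e-9)


class TestPhysicalActivity:
    def test_sedentary_reference(self):
        assert pa_relative_risk(0.0, -0.204) == pytest.approx(1.0)

    def test_reference_dose(self):
        assert pa_relative_risk(11.25, -0.204) == pytest.approx(math.exp(-0.204))

    def test_dose_ratio_sixteenfold(self):
        # (180/11.25) = 16 and 16^0.25 = 2, so the ratio is exp(beta)
        ratio = pa_relative_risk(180.0, -0.204) / pa_relative_risk(11.25, -0.204)
        assert ratio == pytest.approx(math.exp(-0.204), rel=1e-12)

    def test_monotone_nonincreasing(self):
        x = np.linspace(0, 200, 500)
        y = pa_relative_risk(x, -0.204)
        assert (np.diff(y) <= 1e-15).all()

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            pa_relative_risk(-1.0, -0.204)

    @pytest.mark.parametrize(
        "minutes,cat",
        [(0, PACategory.sedentary), (59, PACategory.under_active),
         (60, PACategory.active), (149, PACategory.active),
         (150, PACategory.recommended), (300, PACategory.recommended)],
    )
    def test_categories(self, minutes, cat):
        assert categorize_pa(minutes) == cat

    def test_negative_minutes(self):
        with pytest.raises(ValueError):
            categorize_pa(-5)


class TestMediation:
    def test_bmi_stroke_worked_example(self, ps):
        rr = ps.rr("bmi", "stroke", age=50)            # 1.76 per 5 kg/m^2
        med = ps.mediation("stroke", "bmi", "sbp")     # 0.65 mmHg per kg/m^2
        int_rr = ps.rr("sbp", "stroke", age=45)        # 0.36 per -20 mmHg
        adj = mediation_adjust(rr, med, int_rr)
        expected = 1.76 / (1 / 0.36) ** (3.25 / 20)
        assert adj.value == pytest.approx(expected, rel=1e-9)
        assert adj.value == pytest.approx(1.4909, abs=2e-4)

    def test_zero_coefficient_no_change(self, ps):
        from dataclasses import replace
        rr = ps.rr("bmi", "stroke", age=50)
        med = replace(ps.mediation("stroke", "bmi", "sbp"), coefficient=0.0)
        int_rr = ps.rr("sbp", "stroke", age=45)
        assert mediation_adjust(rr, med, int_rr).value == rr.value

    def test_joint_application_reproduces_total(self, ps):
        """Adjusted direct RR times the RR of the mediated intermediate
        change equals the unadjusted total RR (algebraic identity)."""
        rr = ps.rr("bmi", "stroke", age=50)
        med = ps.mediation("stroke", "bmi", "sbp")
        int_rr = ps.rr("sbp", "stroke", age=45)
        adj = mediation_adjust(rr, med, int_rr)
        delta_sbp = med.coefficient * rr.unit_value  # per 5 kg/m^2
        rr_from_sbp = int_rr.value ** (delta_sbp / int_rr.unit_value)
        assert adj.value * rr_from_sbp == pytest.approx(rr.value, abs=1e-9)


class TestDiabetesCoupling:
    def test_equal_prevalence_gives_one(self):
        assert diabetes_cvd_multiplier(0.08, 0.08, 1.85) == pytest.approx(1.0)

    def test_worked_example(self):
        out = diabetes_cvd_multiplier(0.05, 0.10, 1.85)
        assert out == pytest.approx(1.0425 / 1.0850, rel=1e-9)
        assert out == pytest.approx(0.9608, abs=1e-4)

    def test_rr_one_is_neutral(self):
        assert diabetes_cvd_multiplier(0.30, 0.01, 1.0) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            diabetes_cvd_multiplier(0.1, 0.1, -1.0)
        with pytest.raises(ValueError):
            diabetes_cvd_multiplier(1.5, 0.1, 1.85)


class TestDeconfound:
    def test_zero_fraction_identity(self):
        assert pa_rr_deconfound(-0.204, 0.0) == -0.204

    def test_quarter_fraction(self):
        assert pa_rr_deconfound(-0.204, 0.25) == pytest.approx(-0.153)

    def test_composite_reproduces_total_at_reference_dose(self):
        beta_total, frac = -0.204, 0.25
        beta_direct = pa_rr_deconfound(beta_total, frac)
        beta_mediated = beta_total * frac
        composite = math.exp(beta_direct) * math.exp(beta_mediated)
        assert composite == pytest.approx(math.exp(beta_total), abs=1e-6)

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            pa_rr_deconfound(-0.204, 1.0)


class TestPIF:
    def test_identical_distributions_zero(self, ps):
        rr = ps.rr("red_meat", "colorectal_cancer")
        fn = rr_function([rr], ps.tmin("red_meat").value)
        assert pif_truncnorm(70, 30, 70, 30, fn) == pytest.approx(0.0, abs=1e-15)

    def test_flat_rr_zero(self):
        fn = lambda x: np.ones_like(x)
        assert pif_truncnorm(70, 30, 50, 30, fn) == pytest.approx(0.0, abs=1e-15)

    def test_point_mass_closed_form(self, ps):
        rr = ps.rr("red_meat", "colorectal_cancer")
        fn = rr_function([rr], ps.tmin("red_meat").value)
        pif = pif_truncnorm(114.3, 0.0, 14.3, 0.0, fn)
        assert pif == pytest.approx(1 - 1 / 1.30, rel=1e-9)

    def test_nonconsumer_mixture(self, ps):
        rr = ps.rr("fruit", "ihd")
        tmin = ps.tmin("fruit").value
        fn = rr_function([rr], tmin)
        # all-nonconsumer population sits at zero intake
        pif_all_zero = pif_truncnorm(150, 0.0, 150, 0.0, fn,
                                     nonconsumer_b=1.0, nonconsumer_s=0.0)
        rr0 = float(fn(np.array([0.0]))[0])
        rr150 = float(fn(np.array([150.0]))[0])
        assert pif_all_zero == pytest.approx(1 - rr150 / rr0, rel=1e-9)

    def test_monte_carlo_oracle_single_case(self, ps, rng):
        rr = ps.rr("red_meat", "colorectal_cancer")
        tmin = ps.tmin("red_meat").value
        fn = rr_function([rr], tmin)
        mean_b, sd_b, mean_s, sd_s = 75.0, 32.0, 60.0, 32.0
        pif = pif_truncnorm(mean_b, sd_b, mean_s, sd_s, fn)
        n = 10**6
        draws_b = _truncnorm_draws(mean_b, sd_b, n, rng)
        draws_s = _truncnorm_draws(mean_s, sd_s, n, rng)
        rb, rs = fn(draws_b), fn(draws_s)
        pif_mc = (rb.mean() - rs.mean()) / rb.mean()
        se = _pif_mc_se(rb, rs)
        assert abs(pif - pif_mc) < 3 * se

    @given(shift=st.floats(min_value=0.0, max_value=40.0))
    @settings(max_examples=25, deadline=None)
    def test_direction_of_benefit(self, ps, shift):
        """Moving a harmful exposure toward its minimum gives PIF >= 0,
        moving away gives PIF <= 0."""
        rr = ps.rr("red_meat", "colorectal_cancer")
        fn = rr_function([rr], ps.tmin("red_meat").value)
        toward = pif_truncnorm(80, 25, 80 - shift, 25, fn)
        away = pif_truncnorm(80, 25, 80 + shift, 25, fn)
        assert toward >= -1e-12
        assert away <= 1e-12


def _truncnorm_draws(mean, sd, n, rng):
    hi = mean + 4 * sd
    a, b = (0 - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)


def _pif_mc_se(rb, rs):
    n = len(rb)
    eb, es = rb.mean(), rs.mean()
    var = (rs.var() / n) / eb**2 + (es**2 / eb**4) * (rb.var() / n)
    return np.sqrt(var)
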