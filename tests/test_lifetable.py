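"""Illness-death stepping, case-fatality derivation, and the cohort engine."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msltce.lifetable import (
    DiseaseEpi,
    MainLifeTable,
    apply_pifs,
    derive_case_fatality,
    run_mslt,
    step_disease,
)


class TestCaseFatality:
    def test_ratio_definition(self):
        res = derive_case_fatality(np.array([0.01]), np.array([0.05]),
                                   np.array([0.001]))
        assert res.case_fatality[0] == pytest.approx(0.02)

    def test_zero_mortality(self):
        res = derive_case_fatality(np.array([0.01]), np.array([0.05]),
                                   np.array([0.0]))
        assert res.case_fatality[0] == 0.0

    def test_zero_prevalence_with_mortality_rejected(self):
        with pytest.raises(ValueError):
            derive_case_fatality(np.array([0.01]), np.array([0.0]),
                                 np.array([0.001]))

    def test_steady_state_prevalence(self):
        """Constant incidence 0.01 and case fatality 0.1 drive prevalence to
        the ODE steady state i/(i+f)."""
        from scipy.integrate import solve_ivp
        i, f = 0.01, 0.1
        sol = solve_ivp(lambda t, p: i * (1 - p) - f * p, (0, 400), [0.0],
                        rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(i / (i + f), rel=1e-6)
        assert i / (i + f) == pytest.approx(0.0909, abs=1e-4)

    def test_residual_near_zero_for_consistent_inputs(self, small_fixture):
        epi, _, _ = small_fixture
        for d in epi.diseases:
            m = epi.case_fatality[d] * epi.prevalence[d]
            res = derive_case_fatality(epi.incidence[d], epi.prevalence[d], m)
            assert np.abs(res.residual[:, :-1]).max() < 5e-3


class TestStepDisease:
    def test_no_rates_no_change(self):
        state = (np.array([0.9]), np.array([0.1]), np.array([0.0]))
        (h, p, d), deaths, new = step_disease(state, np.array([0.0]), np.array([0.0]))
        assert h[0] == 0.9 and p[0] == 0.1 and d[0] == 0.0
        assert deaths[0] == 0.0 and new[0] == 0.0

    def test_euler_oracle(self):
        """Exact one-year transition matches a fine-substep Euler scheme."""
        i, f = 0.1, 0.2
        (h, p, d), _, _ = step_disease(
            (np.array([1.0]), np.array([0.0]), np.array([0.0])),
            np.array([i]), np.array([f]))
        he, pe = 1.0, 0.0
        n = 100_000
        dt = 1.0 / n
        for _ in range(n):
            he, pe = he - i * he * dt, pe + (i * he - f * pe) * dt
        assert p[0] == pytest.approx(pe, abs=1e-6)
        assert h[0] == pytest.approx(he, abs=1e-6)

    def test_equal_rates_limit(self):
        i = f = 0.15
        (h, p, d), _, _ = step_disease(
            (np.array([1.0]), np.array([0.0]), np.array([0.0])),
            np.array([i]), np.array([f]))
        assert p[0] == pytest.approx(i * np.exp(-i), rel=1e-9)

    def test_trend_compounds(self):
        i = 0.02
        (_, p1, _), _, _ = step_disease(
            (np.array([1.0]), np.array([0.0]), np.array([0.0])),
            np.array([i]), np.array([0.0]), trend_multiplier=1.1**3)
        (_, p2, _), _, _ = step_disease(
            (np.array([1.0]), np.array([0.0]), np.array([0.0])),
            np.array([i * 1.1**3]), np.array([0.0]))
        assert p1[0] == pytest.approx(p2[0], rel=1e-12)

    @given(
        i=st.floats(min_value=0.0, max_value=0.4),
        f=st.floats(min_value=0.0, max_value=0.4),
        p0=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation(self, i, f, p0):
        state = (np.array([1.0 - p0]), np.array([p0]), np.array([0.0]))
        (h, p, d), deaths, new = step_disease(state, np.array([i]), np.array([f]))
        assert h[0] + p[0] + d[0] == pytest.approx(1.0, abs=1e-9)
        assert deaths[0] >= -1e-12 and new[0] >= -1e-12

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            step_disease((np.array([1.0]), np.array([0.0]), np.array([0.0])),
                         np.array([-0.1]), np.array([0.0]))


class TestApplyPifs:
    def _epi(self):
        ages = np.arange(60, 62)
        arr = lambda v: np.full((2, 2), v)
        return DiseaseEpi(("ihd",), ages, {"ihd": arr(0.01)},
                          {"ihd": arr(0.05)}, {"ihd": arr(0.1)})

    def test_zero_pif_identity(self):
        epi = self._epi()
        out = apply_pifs(epi, {"ihd": np.zeros((2, 2))})
        assert np.array_equal(out.incidence["ihd"], epi.incidence["ihd"])

    def test_single_pif(self):
        out = apply_pifs(self._epi(), {"ihd": np.full((2, 2), 0.2)})
        assert out.incidence["ihd"] == pytest.approx(0.008)

    def test_multiplicative_combination(self):
        from msltce.riskmodel import combine_pifs
        combined = combine_pifs([np.full((2, 2), 0.2), np.full((2, 2), 0.1)])
        out = apply_pifs(self._epi(), {"ihd": combined})
        assert out.incidence["ihd"] == pytest.approx(0.01 * 0.72)

    def test_case_fatality_untouched(self):
        out = apply_pifs(self._epi(), {"ihd": np.full((2, 2), 0.5)})
        assert np.array_equal(out.case_fatality["ihd"],
                              self._epi().case_fatality["ihd"])

    def test_axis_mismatch(self):
        with pytest.raises(ValueError, match="axes"):
            apply_pifs(self._epi(), {"ihd": np.zeros((2, 5))})


class TestRunMSLT:
    def test_null_scenario_identical(self, small_fixture):
        epi, mlt, _ = small_fixture
        tb, ts = run_mslt(epi, epi.copy(), mlt, horizon=10)
        assert np.array_equal(tb.alive, ts.alive)
        assert tb.life_years == ts.life_years
        for d in epi.diseases:
            assert np.array_equal(tb.prevalence[d], ts.prevalence[d])

    def test_geometric_life_years(self):
        """One cohort, constant mortality, no disease: life years are the
        closed-form geometric sum l0 * sum_y exp(-m y)."""
        ages = np.array([60])
        m = 0.05
        epi = DiseaseEpi((), ages, {}, {}, {})
        mlt = MainLifeTable(ages, np.array([[1000.0], [1000.0]]),
                            np.full((2, 1), m))
        tb, _ = run_mslt(epi, epi, mlt, horizon=10)
        expected = 2 * 1000.0 * sum(np.exp(-m * y) for y in range(10))
        assert tb.life_years == pytest.approx(expected, abs=1e-9)

    def test_horizon_year_count(self, small_fixture):
        epi, mlt, _ = small_fixture
        tb, _ = run_mslt(epi, epi.copy(), mlt, horizon=10)
        assert tb.person_years.shape[-1] == 10
        assert len(tb.life_years_by_year()) == 10

    def test_beneficial_pifs_gain_life_years(self, small_fixture):
        epi, mlt, _ = small_fixture
        pifs = {d: np.full((2, len(epi.ages)), 0.15) for d in epi.diseases}
        scen = apply_pifs(epi, pifs)
        for horizon in (1, 5, 10, 20, 100):
            tb, ts = run_mslt(epi, scen, mlt, horizon=horizon)
            assert ts.life_years >= tb.life_years

    def test_prevalence_reproduces_baseline_inputs(self, small_fixture):
        """With flat trends and a null scenario the simulated prevalence
        tracks the (internally consistent) input prevalence."""
        epi, mlt, _ = small_fixture
        tb, _ = run_mslt(epi, epi.copy(), mlt, horizon=9)
        age_min = int(epi.ages[0])
        for d in epi.diseases:
            for y in range(9):
                attained = epi.ages + y
                ok = attained <= int(epi.ages[-1])
                sim = tb.prevalence[d][:, ok, y]
                inp = epi.prevalence[d][:, (attained - age_min)[ok]]
                assert np.abs(sim - inp).max() < 5e-3

    def test_diabetes_coupling_reduces_cvd(self):
        """Lower diabetes incidence in the scenario must feed through to
        lower IHD incidence than PIF-free machinery would give."""
        ages = np.arange(50, 60)
        n = len(ages)
        arr = lambda v: np.full((2, n), v)
        diseases = ("diabetes", "ihd")
        epi = DiseaseEpi(diseases, ages,
                         {"diabetes": arr(0.01), "ihd": arr(0.005)},
                         {"diabetes": arr(0.10), "ihd": arr(0.03)},
                         {"diabetes": arr(0.02), "ihd": arr(0.05)})
        mlt = MainLifeTable(ages, arr(1000.0), arr(0.02))
        scen = apply_pifs(epi, {"diabetes": arr(0.5)})
        rr_dm = {"male": 1.85, "female": 2.63}
        tb, ts_coupled = run_mslt(epi, scen, mlt, horizon=20, rr_dm=rr_dm)
        _, ts_plain = run_mslt(epi, scen, mlt, horizon=20)
        end = 19
        assert (ts_coupled.prevalence["ihd"][:, :, end]
                < ts_plain.prevalence["ihd"][:, :, end] + 1e-12).all()
        assert (ts_coupled.prevalence["ihd"][:, 0, end]
                < tb.prevalence["ihd"][:, 0, end]).all()

    def test_invalid_horizon(self, small_fixture):
        epi, mlt, _ = small_fixture
        with pytest.raises(ValueError):
            run_mslt(epi, epi, mlt, horizon=0)
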