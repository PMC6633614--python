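"""Synthetic baseline inputs: population, all-cause mortality, per-disease
epidemiology, and exposure survey summaries.

The generator exists so the whole pipeline can run and be tested without any
external data download. It emulates the *shape* of the real inputs (Gompertz
all-cause mortality, exponentially age-increasing disease incidence and case
fatality, survey-style exposure means and SDs by age and sex) and is
internally consistent by construction: prevalence is obtained by forward
integration of the illness-death relation dP/da = i (1 - P) - f P, so the
case-fatality identity f = m/P holds with near-zero residual. It makes no
claim of statistical realism beyond that, and is not calibrated to any
actual population.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import DISEASES
from .lifetable import AGES, DiseaseEpi, MainLifeTable
from .riskmodel import MET_TRUNCATION, ExposureDistribution

__all__ = ["PROFILES", "generate_baseline_epi", "generate_exposure_survey"]

#: Fixture profiles: (diseases, ages). "small" runs in well under a second.
PROFILES = {
    "small": (("ihd", "stroke"), np.arange(60, 70)),
    "full": (DISEASES, AGES),
}

# per-disease incidence level at age 15 (/py) and exponential age slope,
# chosen to give plausible adult incidence and prevalence magnitudes
_DISEASE_SHAPES: dict[str, tuple[float, float, float]] = {
    # disease: (incidence at 15, age slope, case fatality at 15)
    "ihd": (2.0e-5, 0.085, 0.004),
    "stroke": (1.0e-5, 0.090, 0.006),
    "diabetes": (3.0e-4, 0.045, 0.001),
    "breast_cancer": (2.0e-5, 0.055, 0.004),
    "colorectal_cancer": (4.0e-6, 0.080, 0.008),
    "lung_cancer": (2.0e-6, 0.090, 0.060),
    "stomach_cancer": (1.0e-6, 0.085, 0.030),
    "liver_cancer": (8.0e-7, 0.085, 0.080),
    "kidney_cancer": (1.5e-6, 0.075, 0.015),
    "pancreatic_cancer": (8.0e-7, 0.090, 0.120),
    "liver_cirrhosis": (2.0e-5, 0.050, 0.015),
}

_SEX_FACTORS = {"male": 1.15, "female": 0.87}


def _integrate_prevalence(inc: np.ndarray, cf: np.ndarray, ages: np.ndarray,
                          substeps: int = 200) -> np.ndarray:
    """Forward RK4 integration of dP/da = i(1-P) - fP from the first age,
    with rates held piecewise-constant per single year of age."""
    prev = np.zeros_like(inc)
    p = 0.0
    dt = 1.0 / substeps
    for ai in range(len(ages)):
        prev[ai] = p
        i, f = inc[ai], cf[ai]

        def rhs(pp: float) -> float:
            return i * (1.0 - pp) - f * pp

        for _ in range(substeps):
            k1 = rhs(p)
            k2 = rhs(p + 0.5 * dt * k1)
            k3 = rhs(p + 0.5 * dt * k2)
            k4 = rhs(p + dt * k3)
            p = p + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    return prev


def generate_baseline_epi(
    diseases: Sequence[str] | None = None,
    seed: int = 0,
    profile: str = "full",
    ages: np.ndarray | None = None,
    rate_scales: Mapping[str, float] | None = None,
) -> tuple[DiseaseEpi, MainLifeTable]:
    """Generate a consistent (DiseaseEpi, MainLifeTable) pair.

    ``rate_scales`` multiplies a disease's incidence level (for stress
    tests); the per-age prevalence is always re-integrated so consistency
    is preserved. Deterministic under ``seed``."""
    prof_d, prof_a = PROFILES[profile]
    diseases = tuple(diseases) if diseases is not None else tuple(prof_d)
    ages = np.asarray(ages) if ages is not None else prof_a.copy()
    if ages[0] < 15 or ages[-1] > 100:
        raise ValueError("ages must lie within 15-100")
    rng = np.random.default_rng(seed)
    rate_scales = dict(rate_scales or {})

    inc: dict[str, np.ndarray] = {}
    prev: dict[str, np.ndarray] = {}
    cf: dict[str, np.ndarray] = {}
    n = len(ages)
    rel_age = ages - 15.0
    disease_mort = np.zeros((2, n))
    for d in diseases:
        i0, slope, f0 = _DISEASE_SHAPES[d]
        i0 *= rate_scales.get(d, 1.0) * float(rng.lognormal(0.0, 0.05))
        inc[d] = np.zeros((2, n))
        prev[d] = np.zeros((2, n))
        cf[d] = np.zeros((2, n))
        for si, sex in enumerate(("male", "female")):
            sf = _SEX_FACTORS[sex]
            if d == "breast_cancer":
                sf = 0.05 if sex == "male" else 1.0
            i_a = np.minimum(i0 * sf * np.exp(slope * rel_age), 0.25)
            f_a = np.minimum(f0 * np.exp(0.035 * rel_age), 0.6)
            # integrate from age 15 so cohorts starting older carry history
            full_rel = np.arange(15, ages[-1] + 1) - 15.0
            i_full = np.minimum(i0 * sf * np.exp(slope * full_rel), 0.25)
            f_full = np.minimum(f0 * np.exp(0.035 * full_rel), 0.6)
            p_full = _integrate_prevalence(i_full, f_full, np.arange(15, ages[-1] + 1))
            sel = np.asarray(ages) - 15
            inc[d][si] = i_a
            cf[d][si] = f_a
            prev[d][si] = p_full[sel]
            disease_mort[si] += cf[d][si] * prev[d][si]

    pop = np.zeros((2, n))
    mort = np.zeros((2, n))
    for si, sex in enumerate(("male", "female")):
        pop[si] = 10000.0 * np.exp(-0.004 * rel_age)
        other = 4.0e-5 * _SEX_FACTORS[sex] * np.exp(0.092 * rel_age)
        mort[si] = other + disease_mort[si]

    epi = DiseaseEpi(diseases, ages, inc, prev, cf,
                     {d: 1.0 for d in diseases}, {d: 1.0 for d in diseases})
    mlt = MainLifeTable(ages, pop, mort)
    return epi, mlt


# survey-style exposure defaults: (male mean at 15, female mean at 15,
# per-year age slope, SD as fraction of mean, non-consumer share)
_EXPOSURE_SHAPES: dict[str, tuple[float, float, float, float, float]] = {
    "fruit": (105.0, 120.0, 0.5, 0.75, 0.22),
    "vegetables": (125.0, 135.0, 0.5, 0.70, 0.10),
    "fibre": (13.0, 12.0, 0.03, 0.35, 0.0),
    "fibre_cereal": (5.5, 4.8, 0.01, 0.45, 0.0),
    "red_meat": (72.0, 50.0, -0.10, 0.60, 0.0),
    "processed_meat": (32.0, 20.0, -0.08, 0.80, 0.0),
    "salt": (8.4, 6.8, 0.0, 0.32, 0.0),
    "total_fat": (34.5, 34.0, 0.0, 0.18, 0.0),
    "saturated_fat": (12.7, 12.4, 0.0, 0.25, 0.0),
    "mufa": (12.2, 11.8, 0.0, 0.22, 0.0),
    "pufa": (6.1, 6.0, 0.0, 0.28, 0.0),
    "dietary_cholesterol": (0.27, 0.22, 0.0, 0.45, 0.0),
    "total_energy": (9200.0, 7100.0, -8.0, 0.24, 0.0),
    "cholesterol": (4.9, 4.8, 0.012, 0.20, 0.0),
    "sbp": (119.0, 114.0, 0.45, 0.12, 0.0),
    "bmi": (23.5, 23.0, 0.08, 0.17, 0.0),
    "physical_activity": (34.0, 26.0, -0.22, 0.65, 0.0),
}

_MEAN_CAPS = {"sbp": 165.0, "bmi": 29.5, "cholesterol": 6.2,
              "physical_activity": MET_TRUNCATION}


def generate_exposure_survey(
    factors: Sequence[str] | None = None,
    seed: int = 0,
    ages: np.ndarray | None = None,
    profile: str = "full",
) -> dict[str, ExposureDistribution]:
    """Survey-style exposure summaries (mean, SD per age/sex) for the given
    factors. Deterministic under ``seed``; SDs strictly positive; physical
    activity respects the 200 MET h/wk survey truncation; fruit/vegetable
    non-consumer shares lie in [0, 1]."""
    _, prof_a = PROFILES[profile]
    ages = np.asarray(ages) if ages is not None else prof_a.copy()
    factors = tuple(factors) if factors is not None else tuple(_EXPOSURE_SHAPES)
    rng = np.random.default_rng(seed)
    out: dict[str, ExposureDistribution] = {}
    for f in factors:
        if f not in _EXPOSURE_SHAPES:
            raise ValueError(f"unknown risk factor {f!r}")
        m15_m, m15_f, slope, sd_frac, nonc = _EXPOSURE_SHAPES[f]
        rows = []
        jitter = rng.normal(0.0, 0.015, size=(2, len(ages)))
        for si, (sex, m15) in enumerate((("male", m15_m), ("female", m15_f))):
            mean = m15 + slope * (ages - 15.0)
            mean = np.clip(mean, 0.05 * m15, _MEAN_CAPS.get(f, np.inf))
            mean = mean * (1.0 + jitter[si])
            if f == "physical_activity":
                mean = np.minimum(mean, MET_TRUNCATION)
            sd = np.maximum(sd_frac * mean, 1e-6)
            for ai, age in enumerate(ages):
                row = {"sex": sex, "age": int(age), "mean": float(mean[ai]),
                       "sd": float(sd[ai])}
                if nonc > 0:
                    row["nonconsumer"] = float(np.clip(nonc, 0.0, 1.0))
                rows.append(row)
        out[f] = ExposureDistribution(f, pd.DataFrame(rows))
    return out
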