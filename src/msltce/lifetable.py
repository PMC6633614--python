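"""Proportional multistate life table.

A closed cohort aged 15-100 is simulated by single year of age and sex. Each
disease carries its own three-state illness-death process (never diseased,
prevalent, dead of disease) with annual incidence and case-fatality rates;
remission is zero. Disease processes are independent of one another except
for the explicit diabetes -> cardiovascular coupling. All-cause mortality each
simulated year is the baseline other-cause rate plus the disease-specific
mortality implied by the current disease-state proportions, so an intervention
that lowers incidence feeds through to survival, person-years, and costs.

Within a year, transitions use the exact constant-rate solution of the
illness-death generator (not an Euler step), so results are invariant to
sub-annual discretisation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGES",
    "DiseaseEpi",
    "MainLifeTable",
    "CohortTrajectory",
    "CaseFatalityResult",
    "derive_case_fatality",
    "step_disease",
    "apply_pifs",
    "run_mslt",
]

#: Single-year ages simulated (closed adult cohort).
AGES = np.arange(15, 101)

_SEXES = ("male", "female")


@dataclass
class DiseaseEpi:
    """Per-disease incidence, prevalence and case fatality by age and sex.

    Arrays have shape (2 sexes, n_ages). ``trend_incidence`` and
    ``trend_case_fatality`` are annual multiplicative drifts compounding from
    simulation year zero (1.0 = flat)."""

    diseases: tuple[str, ...]
    ages: np.ndarray
    incidence: dict[str, np.ndarray]
    prevalence: dict[str, np.ndarray]
    case_fatality: dict[str, np.ndarray]
    trend_incidence: dict[str, float] = field(default_factory=dict)
    trend_case_fatality: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diseases = tuple(self.diseases)
        for d in self.diseases:
            for name, arr in (("incidence", self.incidence[d]),
                              ("case_fatality", self.case_fatality[d])):
                if (arr < 0).any():
                    raise ValueError(f"negative {name} for {d}")
            pv = self.prevalence[d]
            if ((pv < 0) | (pv > 1)).any():
                raise ValueError(f"prevalence outside [0,1] for {d}")
            self.trend_incidence.setdefault(d, 1.0)
            self.trend_case_fatality.setdefault(d, 1.0)

    def subset(self, diseases: Sequence[str]) -> "DiseaseEpi":
        keep = tuple(d for d in self.diseases if d in set(diseases))
        return DiseaseEpi(
            keep, self.ages,
            {d: self.incidence[d] for d in keep},
            {d: self.prevalence[d] for d in keep},
            {d: self.case_fatality[d] for d in keep},
            {d: self.trend_incidence[d] for d in keep},
            {d: self.trend_case_fatality[d] for d in keep},
        )

    def copy(self) -> "DiseaseEpi":
        return DiseaseEpi(
            self.diseases, self.ages,
            {d: self.incidence[d].copy() for d in self.diseases},
            {d: self.prevalence[d].copy() for d in self.diseases},
            {d: self.case_fatality[d].copy() for d in self.diseases},
            dict(self.trend_incidence), dict(self.trend_case_fatality),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.diseases:
            for si, sex in enumerate(_SEXES):
                for ai, age in enumerate(self.ages):
                    rows.append({
                        "disease": d, "sex": sex, "age": int(age),
                        "incidence": self.incidence[d][si, ai],
                        "prevalence": self.prevalence[d][si, ai],
                        "case_fatality": self.case_fatality[d][si, ai],
                        "trend": self.trend_incidence[d],
                    })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DiseaseEpi":
        diseases = tuple(dict.fromkeys(df["disease"]))
        ages = np.sort(df["age"].unique())
        inc, prev, cf, tr = {}, {}, {}, {}
        for d in diseases:
            sub = df[df["disease"] == d]
            inc[d] = np.zeros((2, len(ages)))
            prev[d] = np.zeros((2, len(ages)))
            cf[d] = np.zeros((2, len(ages)))
            for si, sex in enumerate(_SEXES):
                ss = sub[sub["sex"] == sex].sort_values("age")
                inc[d][si] = ss["incidence"].to_numpy(float)
                prev[d][si] = ss["prevalence"].to_numpy(float)
                cf[d][si] = ss["case_fatality"].to_numpy(float)
            tr[d] = float(sub["trend"].iloc[0]) if "trend" in sub.columns else 1.0
        return cls(diseases, ages, inc, prev, cf, tr, dict(tr))


@dataclass
class MainLifeTable:
    """Population counts and all-cause mortality rates by age and sex."""

    ages: np.ndarray
    population: np.ndarray  # (2, n_ages)
    mortality: np.ndarray   # (2, n_ages), /person-year

    def __post_init__(self) -> None:
        if (self.population < 0).any():
            raise ValueError("negative population")
        if (self.mortality < 0).any():
            raise ValueError("negative mortality rate")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for si, sex in enumerate(_SEXES):
            for ai, age in enumerate(self.ages):
                rows.append({"sex": sex, "age": int(age),
                             "population": self.population[si, ai],
                             "mortality": self.mortality[si, ai]})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MainLifeTable":
        ages = np.sort(df["age"].unique())
        pop = np.zeros((2, len(ages)))
        mort = np.zeros((2, len(ages)))
        for si, sex in enumerate(_SEXES):
            ss = df[df["sex"] == sex].sort_values("age")
            pop[si] = ss["population"].to_numpy(float)
            mort[si] = ss["mortality"].to_numpy(float)
        return cls(ages, pop, mort)


@dataclass
class CohortTrajectory:
    """Year-by-year state of one simulated scenario.

    Cohorts are indexed by starting age; a cohort starting at age a has
    attained age a + y in simulated year y and is dropped past age 100.
    ``alive`` holds start-of-year counts (shape (2, n_cohorts, horizon + 1)).
    Disease prevalence and incident proportions are among the alive."""

    label: str
    start_ages: np.ndarray
    horizon: int
    diseases: tuple[str, ...]
    alive: np.ndarray
    person_years: np.ndarray
    mortality_rate: np.ndarray
    prevalence: dict[str, np.ndarray]
    new_cases: dict[str, np.ndarray]
    disease_deaths: dict[str, np.ndarray]

    def active(self, year: int) -> np.ndarray:
        """Mask of cohorts still within the simulated age range in ``year``."""
        return (self.start_ages + year) <= 100

    def attained_ages(self, year: int) -> np.ndarray:
        return self.start_ages + year

    @property
    def life_years(self) -> float:
        return float(self.person_years.sum())

    def life_years_by_year(self) -> np.ndarray:
        return self.person_years.sum(axis=(0, 1))

    def prevalent_persons(self, disease: str) -> np.ndarray:
        """Prevalent case counts, shape (2, n_cohorts, horizon)."""
        return self.prevalence[disease] * self.person_years


@dataclass
class CaseFatalityResult:
    case_fatality: np.ndarray
    residual: np.ndarray


def derive_case_fatality(
    incidence: np.ndarray,
    prevalence: np.ndarray,
    disease_mortality: np.ndarray,
    all_cause_mortality: np.ndarray | None = None,
) -> CaseFatalityResult:
    """Case fatality (annual mortality rate among prevalent cases) from
    disease-specific mortality and prevalence: f = m / P.

    Also reports the residual of the illness-death recursion
    dP/da = i (1 - P) - f P on the age grid, a diagnostic of how internally
    consistent the three inputs are (an external consistency-fitting tool is
    deliberately not reimplemented here)."""
    inc = np.asarray(incidence, float)
    prev = np.asarray(prevalence, float)
    mort = np.asarray(disease_mortality, float)
    if ((prev <= 0) & (mort > 0)).any():
        raise ValueError("positive disease mortality with zero prevalence")
    with np.errstate(divide="ignore", invalid="ignore"):
        cf = np.where(prev > 0, mort / np.where(prev > 0, prev, 1.0), 0.0)
    dp = np.diff(prev, axis=-1)
    mid = slice(None, -1)
    resid = np.zeros_like(prev)
    resid[..., :-1] = dp - (inc[..., mid] * (1 - prev[..., mid]) - cf[..., mid] * prev[..., mid])
    return CaseFatalityResult(case_fatality=cf, residual=resid)


def step_disease(
    state: tuple[np.ndarray, np.ndarray, np.ndarray],
    incidence: np.ndarray,
    case_fatality: np.ndarray,
    trend_multiplier: float | np.ndarray = 1.0,
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], np.ndarray, np.ndarray]:
    """One-year transition of the (healthy, diseased, dead) proportions.

    Uses the exact solution of the constant-rate generator over one year:
    h(1) = h e^{-i};  p(1) = p e^{-f} + h i (e^{-i} - e^{-f})/(f - i),
    with the i -> f limit h i e^{-i}. Returns the new state, the disease
    deaths during the year, and the newly incident proportion."""
    h, p, dead = (np.asarray(a, dtype=float) for a in state)
    i = np.asarray(incidence, dtype=float) * trend_multiplier
    f = np.asarray(case_fatality, dtype=float)
    if (i < 0).any() or (f < 0).any():
        raise ValueError("negative rates")
    eh = np.exp(-i)
    ef = np.exp(-f)
    diff = f - i
    near = np.abs(diff) < 1e-10
    safe = np.where(near, 1.0, diff)
    transfer = np.where(near, i * eh, i * (eh - ef) / safe)
    h1 = h * eh
    p1 = p * ef + h * transfer
    new_cases = h - h1
    deaths = (h + p) - (h1 + p1)
    dead1 = dead + deaths
    if ((h1 < -1e-12) | (p1 < -1e-12) | (h1 > 1 + 1e-12) | (p1 > 1 + 1e-12)).any():
        raise FloatingPointError("disease-state proportions left [0,1]")
    return (h1, p1, dead1), deaths, new_cases


def apply_pifs(
    epi: DiseaseEpi,
    pifs: Mapping[str, np.ndarray],
    dm_multiplier: Mapping[str, np.ndarray] | None = None,
) -> DiseaseEpi:
    """Scale incidence by the combined PIFs (and an optional static diabetes
    multiplier for IHD/stroke); case fatality is untouched - the model only
    moves disease incidence, never survival once diseased."""
    out = epi.copy()
    for d, pif in pifs.items():
        if d not in out.incidence:
            continue
        pif = np.asarray(pif, float)
        if pif.shape != out.incidence[d].shape:
            raise ValueError(f"PIF axes mismatch for {d}: {pif.shape}")
        out.incidence[d] = out.incidence[d] * (1.0 - pif)
    if dm_multiplier:
        for d in ("ihd", "stroke"):
            if d in out.incidence and d in dm_multiplier:
                out.incidence[d] = out.incidence[d] * np.asarray(dm_multiplier[d], float)
    return out


def _simulate(
    epi: DiseaseEpi,
    mlt: MainLifeTable,
    horizon: int,
    label: str,
    m_other: np.ndarray,
    rr_dm: Mapping[str, float] | None = None,
    dm_prev_reference: np.ndarray | None = None,
    trend_decay_year: int | None = None,
) -> CohortTrajectory:
    from .riskmodel import diabetes_cvd_multiplier

    ages = epi.ages
    n_c = len(ages)
    n_d = len(epi.diseases)
    age_min = int(ages[0])
    H = horizon

    alive = np.zeros((2, n_c, H + 1))
    alive[:, :, 0] = mlt.population
    py = np.zeros((2, n_c, H))
    mrate = np.zeros((2, n_c, H))
    prev_out = {d: np.zeros((2, n_c, H)) for d in epi.diseases}
    newc_out = {d: np.zeros((2, n_c, H)) for d in epi.diseases}
    deaths_out = {d: np.zeros((2, n_c, H)) for d in epi.diseases}
    dm_prev_track = np.zeros((2, n_c, H))

    # disease process state per disease/sex/cohort
    h = np.zeros((n_d, 2, n_c))
    p = np.zeros((n_d, 2, n_c))
    dd = np.zeros((n_d, 2, n_c))
    for di, d in enumerate(epi.diseases):
        p[di] = epi.prevalence[d]
        h[di] = 1.0 - p[di]

    has_dm = "diabetes" in epi.diseases
    dm_idx = epi.diseases.index("diabetes") if has_dm else -1

    for y in range(H):
        attained = ages + y
        act = attained <= 100
        if not act.any():
            break
        aidx = np.clip(attained - age_min, 0, n_c - 1)

        def _trend(t: float) -> float:
            yy = y if trend_decay_year is None else min(y, trend_decay_year)
            return float(t) ** yy

        # start-of-year prevalence among alive, per disease
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = h + p
            prev_alive = np.where(denom > 0, p / np.where(denom > 0, denom, 1.0), 0.0)

        if has_dm:
            dm_prev_track[:, :, y] = prev_alive[dm_idx]

        total_extra = np.zeros((2, n_c))
        for di, d in enumerate(epi.diseases):
            i_eff = epi.incidence[d][:, aidx] * _trend(epi.trend_incidence[d])
            f_eff = epi.case_fatality[d][:, aidx] * _trend(epi.trend_case_fatality[d])
            if (
                rr_dm is not None
                and dm_prev_reference is not None
                and has_dm
                and d in ("ihd", "stroke")
            ):
                for si, sex in enumerate(_SEXES):
                    mult = diabetes_cvd_multiplier(
                        np.clip(prev_alive[dm_idx, si], 0, 1),
                        np.clip(dm_prev_reference[si, :, y], 0, 1),
                        rr_dm[sex],
                    )
                    i_eff[si] = i_eff[si] * mult
            i_eff = np.where(act, i_eff, 0.0)
            f_eff = np.where(act, f_eff, 0.0)

            prev_out[d][:, :, y] = np.where(act, prev_alive[di], 0.0)
            total_extra += f_eff * prev_alive[di]

            (h[di], p[di], dd[di]), deaths, newc = step_disease(
                (h[di], p[di], dd[di]), i_eff, f_eff
            )
            newc_out[d][:, :, y] = np.where(act, newc, 0.0)
            deaths_out[d][:, :, y] = np.where(act, deaths, 0.0)

        m_total = np.where(act, m_other[:, aidx] + total_extra, 0.0)
        mrate[:, :, y] = m_total
        py[:, :, y] = np.where(act, alive[:, :, y], 0.0)
        alive[:, :, y + 1] = np.where(act, alive[:, :, y] * np.exp(-m_total), 0.0)

    traj = CohortTrajectory(
        label=label, start_ages=ages.copy(), horizon=H, diseases=epi.diseases,
        alive=alive, person_years=py, mortality_rate=mrate,
        prevalence=prev_out, new_cases=newc_out, disease_deaths=deaths_out,
    )
    traj._dm_prev = dm_prev_track  # reference for the scenario run
    return traj


def run_mslt(
    baseline: DiseaseEpi,
    scenario: DiseaseEpi,
    mlt: MainLifeTable,
    horizon: int = 10,
    rr_dm: Mapping[str, float] | None = None,
    trend_decay_year: int | None = None,
) -> tuple[CohortTrajectory, CohortTrajectory]:
    """Run baseline and scenario cohorts with identical machinery.

    Baseline other-cause mortality is the input all-cause rate minus the
    disease-specific mortality implied by the baseline disease tables
    (floored at zero); both runs then rebuild all-cause mortality each year
    from their own disease states. When ``rr_dm`` is given (RR of
    cardiovascular disease given diabetes, per sex), the scenario's IHD and
    stroke incidence is rescaled each year by the ratio of population-average
    diabetes risk between scenario and baseline."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if tuple(baseline.diseases) != tuple(scenario.diseases):
        raise ValueError("baseline and scenario must model the same diseases")
    if len(baseline.ages) and (baseline.ages[0] < 15 or baseline.ages[-1] > 100):
        raise ValueError("cohort ages must lie within 15-100")

    disease_mort = np.zeros_like(mlt.mortality)
    for d in baseline.diseases:
        disease_mort += baseline.case_fatality[d] * baseline.prevalence[d]
    m_other = np.maximum(mlt.mortality - disease_mort, 0.0)

    traj_b = _simulate(baseline, mlt, horizon, "baseline", m_other,
                       trend_decay_year=trend_decay_year)
    dm_ref = getattr(traj_b, "_dm_prev", None) if rr_dm is not None else None
    traj_s = _simulate(scenario, mlt, horizon, "scenario", m_other,
                       rr_dm=rr_dm, dm_prev_reference=dm_ref,
                       trend_decay_year=trend_decay_year)
    return traj_b, traj_s
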