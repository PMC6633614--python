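"""Risk-factor machinery: exposure distributions, interventions, relative-risk
dose-response curves, mediation and diabetes adjustments, and potential impact
fractions (PIFs).

The PIF is the comparative-risk-assessment core: for an exposure with
dose-response RR(x), baseline density f_b and counterfactual density f_s,

    PIF = ( int RR f_b - int RR f_s ) / int RR f_b .

Exposure densities are normal, truncated to [0, mean + 4 SD] and renormalised;
integration is deterministic trapezoid on a fixed grid so results are exactly
reproducible and can be checked against a Monte Carlo oracle. RR is clamped to
1 beyond the theoretical-minimum exposure: moving past the minimum-risk point
earns no extra benefit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import (
    CatalogueError,
    MediationSpec,
    ParameterSet,
    RelativeRiskSpec,
    TheoreticalMinimum,
)

__all__ = [
    "ExposureDistribution",
    "Intervention",
    "PACategory",
    "PIFSet",
    "EnergyBalanceConfig",
    "MET_TRUNCATION",
    "SODIUM_MMOL_PER_G_SALT",
    "PA_REFERENCE_DOSE",
    "apply_intervention",
    "intermediate_shift",
    "relative_risk_at",
    "rr_function",
    "pa_relative_risk",
    "categorize_pa",
    "mediation_adjust",
    "diabetes_cvd_multiplier",
    "pa_rr_deconfound",
    "pif_truncnorm",
    "compute_pif",
    "combine_pifs",
]

#: mmol of sodium per gram of salt (NaCl is 40% Na by mass; Na = 23 g/mol).
SODIUM_MMOL_PER_G_SALT = 17.1

#: Survey truncation for physical activity (MET hours/week).
MET_TRUNCATION = 200.0

#: Reference dose of the quarter-power physical-activity transformation.
PA_REFERENCE_DOSE = 11.25

#: Grid size for deterministic PIF integration (config-settable per call).
DEFAULT_PIF_POINTS = 201

_INTAKE_UNITS = ("g/day",)


@dataclass(frozen=True)
class EnergyBalanceConfig:
    """Linear steady-state stand-in for the energy-balance equations.

    The published model defers to external sex-specific energy-balance
    equations for the total-energy -> body-weight link; those equations are
    not part of this package. Instead a linear steady-state coefficient
    (kg of body weight per kJ/day of sustained intake change, ~1/100 from
    adult energy-expenditure-per-kg estimates) is divided by a reference
    height squared to yield a BMI change. Both knobs are deliberately
    exposed: replace them if you have a better energy model.
    """

    kg_per_kj_day: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.010, "female": 0.010}
    )
    reference_height_m: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.75, "female": 1.62}
    )

    def bmi_per_kj_day(self, sex: str) -> float:
        return self.kg_per_kj_day[sex] / self.reference_height_m[sex] ** 2


class PACategory(str, Enum):
    sedentary = "sedentary"
    under_active = "under_active"
    active = "active"
    recommended = "recommended"


@dataclass
class ExposureDistribution:
    """Per age/sex mean and SD of one risk factor in its native units.

    ``data`` columns: sex, age, mean, sd and optionally ``nonconsumer``
    (share of the population at zero intake, mixed as a point mass with the
    consumer normal)."""

    risk_factor: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"sex", "age", "mean", "sd"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"exposure table missing columns {sorted(missing)}")
        if (df["sd"].to_numpy(float) < 0).any():
            raise ValueError(f"negative SD in exposure distribution {self.risk_factor!r}")
        if "nonconsumer" in df.columns:
            nc = df["nonconsumer"].to_numpy(float)
            if ((nc < 0) | (nc > 1)).any():
                raise ValueError("non-consumer share outside [0,1]")
        if self.risk_factor == "physical_activity":
            if (df["mean"].to_numpy(float) > MET_TRUNCATION).any():
                raise ValueError(f"MET h/wk above survey truncation {MET_TRUNCATION}")

    def arrays(self, sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        sub = self.data[self.data["sex"] == sex].sort_values("age")
        ages = sub["age"].to_numpy(int)
        mean = sub["mean"].to_numpy(float)
        sd = sub["sd"].to_numpy(float)
        if "nonconsumer" in sub.columns:
            nonc = sub["nonconsumer"].to_numpy(float)
        else:
            nonc = np.zeros_like(mean)
        return ages, mean, sd, nonc

    def mean_at(self, sex: str, age: int) -> float:
        ages, mean, _, _ = self.arrays(sex)
        idx = int(np.argmin(np.abs(ages - age)))
        return float(mean[idx])


@dataclass(frozen=True)
class Intervention:
    """A shift of one risk factor's population mean (SD preserved)."""

    risk_factor: str
    shift_type: str  # absolute | relative | set_mean
    amount: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.shift_type not in ("absolute", "relative", "set_mean"):
            raise ValueError(f"unknown shift type {self.shift_type!r}")
        if not np.isfinite(self.amount):
            raise ValueError("intervention amount must be finite")


@dataclass
class PIFSet:
    """PIF values per disease, keyed arrays of shape (2 sexes, n_ages)."""

    ages: np.ndarray
    sexes: tuple[str, str] = ("male", "female")
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def get(self, disease: str) -> np.ndarray:
        return self.values.get(
            disease, np.zeros((len(self.sexes), len(self.ages)))
        )

    def accumulate(self, disease: str, pif: np.ndarray) -> None:
        """Fold a new PIF into the running multiplicative combination."""
        if (pif > 1 + 1e-12).any():
            raise ValueError("PIF above 1")
        cur = self.get(disease)
        self.values[disease] = 1.0 - (1.0 - cur) * (1.0 - pif)


def apply_intervention(dist: ExposureDistribution, iv: Intervention) -> ExposureDistribution:
    """Shift the mean of ``dist`` per the intervention rule; SD unchanged;
    intakes floored at zero."""
    if iv.risk_factor != dist.risk_factor:
        raise ValueError(
            f"intervention on {iv.risk_factor!r} applied to {dist.risk_factor!r}"
        )
    df = dist.data.copy()
    mean = df["mean"].to_numpy(float)
    if iv.shift_type == "absolute":
        new = mean + iv.amount
    elif iv.shift_type == "relative":
        new = mean * (1.0 + iv.amount)
    else:  # set_mean
        new = np.full_like(mean, iv.amount)
    if not np.all(np.isfinite(new)):
        raise ValueError("intervention produced non-finite exposure mean")
    df["mean"] = np.maximum(new, 0.0)
    return ExposureDistribution(dist.risk_factor, df)


def intermediate_shift(
    diet_changes: Mapping[str, float],
    ps: ParameterSet,
    sex: str = "male",
    energy: EnergyBalanceConfig | None = None,
) -> dict[str, float]:
    """Convert mean dietary changes into changes of the intermediates
    (systolic blood pressure mmHg, total cholesterol mmol/L, BMI kg/m^2).

    Salt in g/day is converted to 24-h urinary sodium (17.1 mmol per gram of
    salt) before the per-100-mmol blood-pressure coefficient applies. The
    total-energy -> BMI link uses the configurable linear stand-in.
    """
    energy = energy or EnergyBalanceConfig()
    out = {"sbp": 0.0, "cholesterol": 0.0, "bmi": 0.0}
    for factor, delta in diet_changes.items():
        if delta == 0:
            continue
        if factor == "total_energy":
            out["bmi"] += energy.bmi_per_kj_day(sex) * delta
            continue
        spec = ps.intermediate_effect(factor)
        if spec.coefficient is None:
            raise CatalogueError(f"no numeric coefficient for {factor!r}")
        if factor == "salt":
            delta = delta * SODIUM_MMOL_PER_G_SALT  # grams -> mmol sodium
        out[spec.intermediate] += spec.coefficient * delta / spec.unit_value
    return out


def _log_rr_slope(spec: RelativeRiskSpec) -> float:
    return math.log(spec.value) / spec.unit_value


def rr_function(
    specs: Sequence[RelativeRiskSpec],
    tmin: float,
    clamp: bool = True,
) -> Callable[[np.ndarray], np.ndarray]:
    """Build RR(x) anchored at the theoretical minimum.

    For a single per-unit spec, log RR(x) = ln(value) * (x - tmin)/unit.
    Exposure-banded specs (e.g. BMI risk differing below/above 25 kg/m^2)
    give a continuous piecewise log-linear curve: the local slope within each
    band is integrated from tmin to x. With ``clamp``, RR is floored at 1 so
    exposure beyond the minimum-risk point earns no extra benefit.
    """
    specs = list(specs)
    if not specs:
        return lambda x: np.ones_like(np.asarray(x, dtype=float))
    if len(specs) == 1 and specs[0].exposure_band is None:
        slope = _log_rr_slope(specs[0])

        def f(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            rr = np.exp(slope * (x - tmin))
            return np.maximum(rr, 1.0) if clamp else rr

        return f

    banded = sorted(specs, key=lambda s: s.exposure_band[0])

    def slope_at(u: np.ndarray) -> np.ndarray:
        s = np.full(u.shape, _log_rr_slope(banded[0]))
        for spec in banded:
            lo, hi = spec.exposure_band
            s = np.where((u >= lo) & (u < hi), _log_rr_slope(spec), s)
        s = np.where(u >= banded[-1].exposure_band[1], _log_rr_slope(banded[-1]), s)
        return s

    def g(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        # integrate slope(u) du from tmin to x, exact for piecewise-constant
        edges = sorted({tmin} | {b for s in banded for b in s.exposure_band})
        logrr = np.zeros_like(x)
        for xi_idx in np.ndindex(x.shape):
            xi = x[xi_idx]
            lo, hi = (tmin, xi) if xi >= tmin else (xi, tmin)
            total = 0.0
            pts = [lo] + [e for e in edges if lo < e < hi] + [hi]
            for a, b in zip(pts, pts[1:]):
                mid = np.asarray([(a + b) / 2.0])
                total += float(slope_at(mid)[0]) * (b - a)
            logrr[xi_idx] = total if xi >= tmin else -total
        rr = np.exp(logrr)
        return np.maximum(rr, 1.0) if clamp else rr

    return g


def relative_risk_at(
    exposure: float,
    rr: RelativeRiskSpec,
    tmin: TheoreticalMinimum | float,
) -> float:
    """RR at a single exposure value versus the theoretical minimum."""
    tmin_value = tmin.value if isinstance(tmin, TheoreticalMinimum) else float(tmin)
    if rr.form == "beta_quarter_power":
        raise ValueError("use pa_relative_risk for quarter-power betas")
    if rr.unit_label in _INTAKE_UNITS and exposure < 0:
        raise ValueError("negative exposure for an intake factor")
    return float(rr_function([rr], tmin_value)(np.asarray([exposure]))[0])


def pa_relative_risk(
    met_hours: float | np.ndarray,
    beta: float,
    reference_dose: float = PA_REFERENCE_DOSE,
    power: float = 0.25,
) -> float | np.ndarray:
    """RR of disease versus sedentary at a physical-activity dose.

    RR(x) = exp(beta * (x / reference)^power); equals 1 at zero dose and
    exp(beta) at the reference dose, monotone non-increasing for beta < 0.
    """
    x = np.asarray(met_hours, dtype=float)
    if (x < 0).any():
        raise ValueError("negative MET hours")
    rr = np.exp(beta * (x / reference_dose) ** power)
    return float(rr) if np.ndim(met_hours) == 0 else rr


def categorize_pa(minutes_moderate_per_week: float) -> PACategory:
    """Activity category from weekly minutes of moderate activity.

    Zero -> sedentary; (0, 60) -> under-active; [60, 150) -> active;
    150+ meets the recommendation."""
    m = float(minutes_moderate_per_week)
    if m < 0:
        raise ValueError("negative minutes of activity")
    if m == 0:
        return PACategory.sedentary
    if m < 60:
        return PACategory.under_active
    if m < 150:
        return PACategory.active
    return PACategory.recommended


def mediation_adjust(
    rr: RelativeRiskSpec,
    med: MediationSpec,
    intermediate_rr: RelativeRiskSpec,
) -> RelativeRiskSpec:
    """Remove the intermediate-mediated share from a total (direct) RR.

    The mediated intermediate change implied by one exposure unit moved in
    the harmful direction is ``med.coefficient`` (scaled to the RR's unit).
    Dividing the total RR by the RR implied by that intermediate change
    leaves a direct RR such that firing both pathways together reproduces
    the original total effect exactly.
    """
    direction = np.sign(math.log(rr.value)) if rr.value != 1.0 else 0.0
    delta_int = direction * med.coefficient * (rr.unit_value / med.unit_value)
    implied = intermediate_rr.value ** (delta_int / intermediate_rr.unit_value)
    return replace(rr, value=rr.value / implied)


def diabetes_cvd_multiplier(
    p_dm_scenario: float | np.ndarray,
    p_dm_baseline: float | np.ndarray,
    rr_dm: float,
) -> float | np.ndarray:
    """Scale IHD/stroke incidence for a change in diabetes prevalence.

    With RR of cardiovascular disease given diabetes r, population average
    risk scales as 1 + p (r - 1), so the incidence multiplier is the ratio
    of scenario to baseline population-average risk."""
    if rr_dm <= 0:
        raise ValueError("diabetes RR must be positive")
    p_s = np.asarray(p_dm_scenario, dtype=float)
    p_b = np.asarray(p_dm_baseline, dtype=float)
    if ((p_s < 0) | (p_s > 1) | (p_b < 0) | (p_b > 1)).any():
        raise ValueError("prevalence outside [0,1]")
    out = (1.0 + p_s * (rr_dm - 1.0)) / (1.0 + p_b * (rr_dm - 1.0))
    return float(out) if np.ndim(p_dm_scenario) == 0 and np.ndim(p_dm_baseline) == 0 else out


def pa_rr_deconfound(beta_total: float, mediated_fraction: float) -> float:
    """Split a total physical-activity beta into its direct component.

    A fraction of the physical-activity effect on cardiovascular disease is
    mediated by diabetes, which the life table models dynamically; leaving
    the total beta in place would double count. The split is linear at the
    reference dose: beta_direct = beta_total * (1 - mediated_fraction)."""
    if not 0.0 <= mediated_fraction < 1.0:
        raise ValueError("mediated fraction must be in [0, 1)")
    return beta_total * (1.0 - mediated_fraction)


def _mean_rr(
    mean: float,
    sd: float,
    rr_fn: Callable[[np.ndarray], np.ndarray],
    nonconsumer: float = 0.0,
    n_points: int = DEFAULT_PIF_POINTS,
    upper: float | None = None,
) -> float:
    """E[RR(X)] under a normal truncated to [0, mean + 4 SD] (renormalised),
    optionally mixed with a point mass at zero."""
    if sd == 0.0:
        core = float(rr_fn(np.asarray([mean]))[0])
    else:
        hi = mean + 4.0 * sd
        if upper is not None:
            hi = min(hi, upper)
        hi = max(hi, 1e-9)
        x = np.linspace(0.0, hi, n_points)
        pdf = np.exp(-0.5 * ((x - mean) / sd) ** 2)
        z = np.trapezoid(pdf, x)
        if not np.isfinite(z) or z <= 0:
            raise FloatingPointError("degenerate exposure density")
        core = float(np.trapezoid(rr_fn(x) * pdf, x) / z)
    if nonconsumer > 0.0:
        zero_rr = float(rr_fn(np.asarray([0.0]))[0])
        core = nonconsumer * zero_rr + (1.0 - nonconsumer) * core
    if not np.isfinite(core):
        raise FloatingPointError("non-finite RR integral")
    return core


def pif_truncnorm(
    mean_b: float,
    sd_b: float,
    mean_s: float,
    sd_s: float,
    rr_fn: Callable[[np.ndarray], np.ndarray],
    nonconsumer_b: float = 0.0,
    nonconsumer_s: float = 0.0,
    n_points: int = DEFAULT_PIF_POINTS,
    upper: float | None = None,
) -> float:
    """PIF for one (baseline, scenario) pair of truncated-normal exposures."""
    eb = _mean_rr(mean_b, sd_b, rr_fn, nonconsumer_b, n_points, upper)
    es = _mean_rr(mean_s, sd_s, rr_fn, nonconsumer_s, n_points, upper)
    return (eb - es) / eb


def compute_pif(
    base: ExposureDistribution,
    scen: ExposureDistribution,
    ps: ParameterSet,
    disease: str,
    ages: np.ndarray,
    rr_specs_by_sex_age: Callable[[str, int], Sequence[RelativeRiskSpec]] | None = None,
    tmin_value: float | None = None,
    n_points: int = DEFAULT_PIF_POINTS,
) -> np.ndarray:
    """PIF array of shape (2, n_ages) for one risk factor and disease.

    Relative-risk specs are selected per sex and age (age-banded specs apply
    uniformly within their band; ages beyond the last band reuse the nearest
    covered band). Returns zeros where no RR is catalogued."""
    factor = base.risk_factor
    if scen.risk_factor != factor:
        raise ValueError("risk-factor mismatch between baseline and scenario")
    if tmin_value is None:
        tmin_value = ps.tmin(factor).value if factor in ps.theoretical_minima else 0.0
    upper = MET_TRUNCATION if factor == "physical_activity" else None
    out = np.zeros((2, len(ages)))
    for si, sex in enumerate(("male", "female")):
        a_b, m_b, s_b, nc_b = base.arrays(sex)
        a_s, m_s, s_s, nc_s = scen.arrays(sex)
        cache: dict[tuple, Callable] = {}
        for ai, age in enumerate(ages):
            if rr_specs_by_sex_age is not None:
                specs = list(rr_specs_by_sex_age(sex, int(age)))
            else:
                specs = _select_specs(ps, factor, disease, sex, int(age))
            if not specs:
                continue
            key = tuple(id(s) for s in specs)
            if key not in cache:
                if specs[0].form == "beta_quarter_power":
                    beta = specs[0].value
                    cache[key] = lambda x, b=beta: pa_relative_risk(x, b)
                else:
                    cache[key] = rr_function(specs, tmin_value)
            fn = cache[key]
            ib = int(np.argmin(np.abs(a_b - age)))
            isc = int(np.argmin(np.abs(a_s - age)))
            out[si, ai] = pif_truncnorm(
                m_b[ib], s_b[ib], m_s[isc], s_s[isc], fn,
                nc_b[ib], nc_s[isc], n_points, upper,
            )
    return out


def _select_specs(
    ps: ParameterSet, factor: str, disease: str, sex: str, age: int
) -> list[RelativeRiskSpec]:
    entries = [r for r in ps.rr_entries(factor, disease) if not (r.sex and r.sex != sex)]
    if not entries:
        return []
    banded = [r for r in entries if r.exposure_band is not None]
    if banded:
        return banded
    hit = [r for r in entries if r.age_band[0] <= age <= r.age_band[1]]
    if hit:
        return hit[:1]
    # age outside every band: reuse the nearest covered band (step function)
    nearest = min(
        entries,
        key=lambda r: min(abs(age - r.age_band[0]), abs(age - r.age_band[1])),
    )
    # ages below the first band carry no effect (e.g. BMI bands starting at 35
    # leave younger ages unaffected); ages above the last band reuse it
    if age < min(r.age_band[0] for r in entries):
        return []
    return [nearest]


def combine_pifs(pifs: Sequence[np.ndarray]) -> np.ndarray:
    """Multiplicative combination on (1 - PIF) across independent factors."""
    out = None
    for p in pifs:
        out = p if out is None else 1.0 - (1.0 - out) * (1.0 - p)
    if out is None:
        raise ValueError("no PIFs to combine")
    return out
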