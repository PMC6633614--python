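"""End-to-end scenario engine.

Wires the stages together: interventions shift exposure distributions; shifts
of diet factors propagate to the intermediates (blood pressure, cholesterol,
BMI); direct and intermediate-pathway PIFs are combined multiplicatively per
disease; the multistate life table turns incidence changes into survival,
person-years and disease-state trajectories; utilities and costs convert the
trajectories into QALY and cost streams; and discounting yields the
cost-effectiveness result.

Double counting is avoided in two places: fruit/vegetable/BMI relative risks
on IHD and stroke are mediation-adjusted (their blood-pressure/cholesterol
share is removed because the intermediate pathway also fires), and the
physical-activity betas on IHD/stroke are deconfounded for the share mediated
via diabetes, which the life table models dynamically.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .catalogue import CatalogueError, ParameterSet, RelativeRiskSpec
from .econ import EconResult, CostStream, build_cost_stream, cost_effectiveness, discount
from .lifetable import CohortTrajectory, DiseaseEpi, MainLifeTable, apply_pifs, run_mslt
from .outcomes import QALYStream, qaly_stream
from .riskmodel import (
    EnergyBalanceConfig,
    ExposureDistribution,
    Intervention,
    apply_intervention,
    compute_pif,
    mediation_adjust,
    pa_rr_deconfound,
    rr_function,
    pa_relative_risk,
    pif_truncnorm,
    MET_TRUNCATION,
    SODIUM_MMOL_PER_G_SALT,
)

__all__ = ["PipelineOptions", "ScenarioResult", "build_pif_tables", "run_pipeline"]

#: Diet factors feeding the intermediate pathway.
_INTERMEDIATE_SOURCES = ("total_fat", "saturated_fat", "mufa", "pufa",
                         "dietary_cholesterol", "salt", "total_energy")
#: Behavioural factors with direct disease relative risks.
_DIRECT_FACTORS = ("fruit", "vegetables", "fibre", "fibre_cereal",
                   "red_meat", "processed_meat", "physical_activity")
_INTERMEDIATES = ("sbp", "cholesterol", "bmi")


@dataclass(frozen=True)
class PipelineOptions:
    """Numerical and structural switches with their defaults.

    ``pa_diabetes_mediated_fraction`` is the share of the physical-activity
    effect on IHD/stroke mediated via diabetes that is stripped from the
    direct beta (the life table restores it dynamically)."""

    pa_diabetes_mediated_fraction: float = 0.10
    energy: EnergyBalanceConfig = field(default_factory=EnergyBalanceConfig)
    diabetes_coupling: bool = True
    incident_utility_decrement: bool = True
    pif_points: int = 201
    trend_decay_year: int | None = None
    mediation_adjustment: bool = True


@dataclass
class ScenarioResult:
    label: str
    horizon: int
    discount_rate: float
    discount_rate_costs: float
    perspective: str
    econ: EconResult
    qalys_baseline: QALYStream
    qalys_scenario: QALYStream
    costs_baseline: CostStream
    costs_scenario: CostStream
    traj_baseline: CohortTrajectory
    traj_scenario: CohortTrajectory
    pifs: dict[str, np.ndarray]

    def delta_cost_components(self) -> dict[str, float]:
        """Discounted per-component cost differences (scenario - baseline)."""
        out = {}
        cb = self.costs_scenario.components()
        ca = self.costs_baseline.components()
        for k in cb:
            out[k] = discount(cb[k], self.discount_rate_costs) - discount(
                ca[k], self.discount_rate_costs)
        return out


def _mediated_intermediate_delta(
    ps: ParameterSet, disease: str, exposure: str, intermediate: str, delta: float
) -> float:
    """Intermediate change implied by an exposure change, using the
    disease-specific mediation coefficient. Positive coefficients describe
    the harmful direction (BMI up; fruit/vegetables down)."""
    try:
        med = ps.mediation(disease, exposure, intermediate)
    except CatalogueError:
        return 0.0
    sign = 1.0 if exposure == "bmi" else -1.0
    return sign * med.coefficient * delta / med.unit_value


def _direct_specs(
    ps: ParameterSet,
    factor: str,
    disease: str,
    sex: str,
    age: int,
    options: PipelineOptions,
) -> list[RelativeRiskSpec]:
    """Per-age direct RR specs, mediation-adjusted where the intermediate
    pathway fires as well (fruit/vegetables on IHD/stroke)."""
    from .riskmodel import _select_specs

    specs = _select_specs(ps, factor, disease, sex, age)
    if not specs or not options.mediation_adjustment:
        return specs
    if factor not in ("fruit", "vegetables") or disease not in ("ihd", "stroke"):
        return specs
    adjusted = []
    for spec in specs:
        cur = spec
        for med in ps.mediations_for(disease, factor):
            try:
                int_rr = ps.rr(med.intermediate, disease, sex=sex, age=age)
            except CatalogueError:
                continue
            cur = mediation_adjust(cur, med, int_rr)
        adjusted.append(cur)
    return adjusted


def _bmi_specs_adjusted(
    ps: ParameterSet, disease: str, sex: str, age: int, options: PipelineOptions
) -> list[RelativeRiskSpec]:
    """BMI RR specs with the blood-pressure-mediated share removed for
    IHD/stroke (the BMI shift also moves the SBP distribution)."""
    from .riskmodel import _select_specs

    specs = _select_specs(ps, "bmi", disease, sex, age)
    if not specs or not options.mediation_adjustment or disease not in ("ihd", "stroke"):
        return specs
    out = []
    for spec in specs:
        cur = spec
        for med in ps.mediations_for(disease, "bmi"):
            try:
                int_rr = ps.rr(med.intermediate, disease, sex=sex, age=age)
            except CatalogueError:
                continue
            cur = mediation_adjust(cur, med, int_rr)
        out.append(cur)
    return out


def _shift_distribution(dist: ExposureDistribution, delta_by_sex_age) -> ExposureDistribution:
    df = dist.data.copy()
    deltas = np.array([
        delta_by_sex_age(row.sex, int(row.age)) for row in df.itertuples(index=False)
    ])
    df["mean"] = np.maximum(df["mean"].to_numpy(float) + deltas, 0.0)
    return ExposureDistribution(dist.risk_factor, df)


def build_pif_tables(
    ps: ParameterSet,
    baseline_exposures: Mapping[str, ExposureDistribution],
    scenario_exposures: Mapping[str, ExposureDistribution],
    diseases: Sequence[str],
    ages: np.ndarray,
    options: PipelineOptions | None = None,
) -> dict[str, np.ndarray]:
    """Combined PIF per disease, shape (2 sexes, n_ages).

    Direct behavioural pathways and intermediate pathways are folded
    multiplicatively on (1 - PIF). Only factors whose baseline and scenario
    distributions differ contribute (identical distributions give PIF 0
    exactly and are skipped)."""
    options = options or PipelineOptions()
    pifs: dict[str, np.ndarray] = {d: np.zeros((2, len(ages))) for d in diseases}

    def changed(f: str) -> bool:
        if f not in scenario_exposures or f not in baseline_exposures:
            return False
        b = baseline_exposures[f].data
        s = scenario_exposures[f].data
        return not np.allclose(b["mean"].to_numpy(float), s["mean"].to_numpy(float))

    def fold(d: str, pif: np.ndarray) -> None:
        pifs[d] = 1.0 - (1.0 - pifs[d]) * (1.0 - pif)

    # --- direct behavioural factors --------------------------------------
    for factor in _DIRECT_FACTORS:
        if not changed(factor):
            continue
        base, scen = baseline_exposures[factor], scenario_exposures[factor]
        for d in diseases:
            if not ps.rr_entries(factor, d):
                continue
            if factor == "physical_activity":
                pif = _pa_pif(ps, base, scen, d, ages, options)
            else:
                tmin_f = "fibre" if factor == "fibre_cereal" else factor
                tmin_value = ps.tmin(tmin_f).value
                pif = compute_pif(
                    base, scen, ps, d, ages,
                    rr_specs_by_sex_age=lambda sex, age, f=factor, dd=d: _direct_specs(
                        ps, f, dd, sex, age, options),
                    tmin_value=tmin_value, n_points=options.pif_points,
                )
            fold(d, pif)

    # --- intermediate pathway --------------------------------------------
    diet_deltas: dict[str, dict[str, np.ndarray]] = {}
    for factor in (*_INTERMEDIATE_SOURCES, "fruit", "vegetables"):
        if not changed(factor):
            continue
        per_sex = {}
        for sex in ("male", "female"):
            a_b, m_b, _, _ = baseline_exposures[factor].arrays(sex)
            _, m_s, _, _ = scenario_exposures[factor].arrays(sex)
            per_sex[sex] = (a_b, m_s - m_b)
        diet_deltas[factor] = per_sex

    if diet_deltas:
        for d in diseases:
            for inter in _INTERMEDIATES:
                specs_exist = bool(ps.rr_entries(inter, d))
                if not specs_exist or inter not in baseline_exposures:
                    continue

                def delta_at(sex: str, age: int, inter=inter, d=d) -> float:
                    total = 0.0
                    for factor, per_sex in diet_deltas.items():
                        a_arr, deltas = per_sex[sex]
                        idx = int(np.argmin(np.abs(a_arr - age)))
                        delta = float(deltas[idx])
                        if delta == 0.0:
                            continue
                        if factor in ("fruit", "vegetables"):
                            if options.mediation_adjustment and d in ("ihd", "stroke"):
                                total += _mediated_intermediate_delta(ps, d, factor, inter, delta)
                            continue
                        spec = ps.intermediate_effects.get(factor)
                        if factor == "total_energy":
                            if inter == "bmi":
                                total += options.energy.bmi_per_kj_day(sex) * delta
                            continue
                        if spec is None or spec.intermediate != inter:
                            continue
                        if factor == "salt":
                            delta = delta * SODIUM_MMOL_PER_G_SALT
                        total += spec.coefficient * delta / spec.unit_value
                    return total

                any_delta = any(
                    abs(delta_at(sex, int(a))) > 0
                    for sex in ("male", "female") for a in ages[:: max(1, len(ages) // 8)]
                ) or any(
                    abs(delta_at(sex, int(a))) > 0
                    for sex in ("male", "female") for a in ages
                )
                if not any_delta:
                    continue
                base_i = baseline_exposures[inter]
                scen_i = _shift_distribution(base_i, delta_at)
                if inter == "bmi":
                    spec_fn = lambda sex, age, dd=d: _bmi_specs_adjusted(
                        ps, dd, sex, age, options)
                else:
                    spec_fn = None
                pif = compute_pif(
                    base_i, scen_i, ps, d, ages,
                    rr_specs_by_sex_age=spec_fn,
                    tmin_value=ps.tmin(inter).value, n_points=options.pif_points,
                )
                fold(d, pif)

    # BMI shift also affects diabetes etc. via its own direct RRs; the
    # intermediate loop above already covers every disease with a BMI RR.
    return pifs


def _pa_pif(
    ps: ParameterSet,
    base: ExposureDistribution,
    scen: ExposureDistribution,
    disease: str,
    ages: np.ndarray,
    options: PipelineOptions,
) -> np.ndarray:
    """Physical-activity PIF with the quarter-power dose-response; the
    IHD/stroke beta is deconfounded for its diabetes-mediated share when the
    dynamic coupling is on."""
    spec = ps.rr("physical_activity", disease)
    beta = spec.value
    if options.diabetes_coupling and disease in ("ihd", "stroke"):
        beta = pa_rr_deconfound(beta, options.pa_diabetes_mediated_fraction)
    out = np.zeros((2, len(ages)))
    for si, sex in enumerate(("male", "female")):
        a_b, m_b, s_b, _ = base.arrays(sex)
        a_s, m_s, s_s, _ = scen.arrays(sex)
        fn = lambda x, b=beta: pa_relative_risk(x, b)
        for ai, age in enumerate(ages):
            ib = int(np.argmin(np.abs(a_b - age)))
            isc = int(np.argmin(np.abs(a_s - age)))
            out[si, ai] = pif_truncnorm(
                m_b[ib], s_b[ib], m_s[isc], s_s[isc], fn,
                n_points=options.pif_points, upper=MET_TRUNCATION,
            )
    return out


def run_pipeline(
    ps: ParameterSet,
    epi: DiseaseEpi,
    mlt: MainLifeTable,
    exposures: Mapping[str, ExposureDistribution],
    interventions: Sequence[Intervention],
    horizon: int = 10,
    discount_rate: float = 0.015,
    discount_rate_costs: float | None = None,
    perspective: str = "nhs_social_care",
    intervention_cost: Sequence[float] | float = 0.0,
    diseases: Sequence[str] | None = None,
    include_unrelated: bool = True,
    productivity: Sequence[float] | None = None,
    wider_societal: Sequence[float] | None = None,
    options: PipelineOptions | None = None,
    label: str = "scenario",
) -> ScenarioResult:
    """Run one intervention scenario against its no-intervention baseline."""
    options = options or PipelineOptions()
    if discount_rate_costs is None:
        discount_rate_costs = discount_rate
    if diseases is not None:
        epi = epi.subset(diseases)

    scen_exposures = dict(exposures)
    for iv in interventions:
        if iv.risk_factor not in exposures:
            raise ValueError(f"no exposure distribution for {iv.risk_factor!r}")
        scen_exposures[iv.risk_factor] = apply_intervention(
            exposures[iv.risk_factor], iv)

    pifs = build_pif_tables(ps, exposures, scen_exposures, epi.diseases,
                            epi.ages, options)
    scen_epi = apply_pifs(epi, pifs)

    rr_dm = None
    if options.diabetes_coupling and "diabetes" in epi.diseases and (
            "ihd" in epi.diseases or "stroke" in epi.diseases):
        rr_dm = {}
        for sex in ("male", "female"):
            rr_dm[sex] = ps.rr("diabetes", "ihd", sex=sex).value
    traj_b, traj_s = run_mslt(epi, scen_epi, mlt, horizon=horizon, rr_dm=rr_dm,
                              trend_decay_year=options.trend_decay_year)

    q_b = qaly_stream(traj_b, ps.utilities, options.incident_utility_decrement)
    q_s = qaly_stream(traj_s, ps.utilities, options.incident_utility_decrement)
    c_b = build_cost_stream(traj_b, ps.utilities, ps.costs, 0.0,
                            np.zeros(horizon), np.zeros(horizon))
    c_s = build_cost_stream(traj_s, ps.utilities, ps.costs, intervention_cost,
                            productivity, wider_societal)

    cost_b = discount(c_b.total(perspective, include_unrelated), discount_rate_costs)
    cost_s = discount(c_s.total(perspective, include_unrelated), discount_rate_costs)
    e_b = discount(q_b.qalys, discount_rate)
    e_s = discount(q_s.qalys, discount_rate)
    ci_total = discount(c_s.intervention, discount_rate_costs)
    econ = cost_effectiveness(
        cost_s, cost_b, e_s, e_b, perspective=perspective, horizon=horizon,
        discount_rate=discount_rate, c_i=ci_total,
    )
    return ScenarioResult(
        label=label, horizon=horizon, discount_rate=discount_rate,
        discount_rate_costs=discount_rate_costs, perspective=perspective,
        econ=econ, qalys_baseline=q_b, qalys_scenario=q_s,
        costs_baseline=c_b, costs_scenario=c_s,
        traj_baseline=traj_b, traj_scenario=traj_s, pifs=pifs,
    )
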