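"""Scenario configuration: YAML schema, validation, and result bundles.

A scenario file describes the inputs (baseline epidemiology and exposures,
real CSVs or the synthetic generator), the intervention (exposure shifts and
their cost), and the analysis settings. Unset settings fall back to the
primary-analysis defaults: 10-year horizon, 1.5% annual discount on both
costs and health outcomes, health-plus-social-care perspective, intervention
costs to government and industry included. Unknown keys are rejected with
the offending key named.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import synthetic_data
from .catalogue import DISEASES, load_catalogue
from .econ import PERSPECTIVES
from .lifetable import DiseaseEpi, MainLifeTable
from .pipeline import PipelineOptions, ScenarioResult, run_pipeline
from .riskmodel import EnergyBalanceConfig, Intervention

__all__ = ["ScenarioConfig", "ConfigError", "load_config", "execute_scenario",
           "write_bundle", "SENSITIVITY_VARIANTS", "sensitivity_variants"]


class ConfigError(ValueError):
    pass


class ShiftSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    type: Literal["absolute", "relative", "set_mean"]
    amount: float


class InterventionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    risk_factor: str
    shift: ShiftSpec


class SyntheticSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    profile: Literal["small", "full"] = "full"
    seed: int = 0


class InputSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    synthetic: Optional[SyntheticSpec] = None
    baseline_epi: Optional[str] = None     # CSV path
    life_table: Optional[str] = None       # CSV path
    exposures: Optional[str] = None        # directory of per-factor CSVs


class OptionsSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pa_diabetes_mediated_fraction: float = 0.10
    diabetes_coupling: bool = True
    incident_utility_decrement: bool = True
    pif_points: int = 201
    trend_decay_year: Optional[int] = None
    mediation_adjustment: bool = True
    energy_kg_per_kj_day: dict[str, float] = Field(
        default_factory=lambda: {"male": 0.010, "female": 0.010})
    energy_reference_height_m: dict[str, float] = Field(
        default_factory=lambda: {"male": 1.75, "female": 1.62})

    def to_pipeline_options(self) -> PipelineOptions:
        return PipelineOptions(
            pa_diabetes_mediated_fraction=self.pa_diabetes_mediated_fraction,
            energy=EnergyBalanceConfig(
                kg_per_kj_day=self.energy_kg_per_kj_day,
                reference_height_m=self.energy_reference_height_m,
            ),
            diabetes_coupling=self.diabetes_coupling,
            incident_utility_decrement=self.incident_utility_decrement,
            pif_points=self.pif_points,
            trend_decay_year=self.trend_decay_year,
            mediation_adjustment=self.mediation_adjustment,
        )


class ScenarioConfig(BaseModel):
    """Full scenario description; defaults are the primary-analysis settings."""

    model_config = ConfigDict(extra="forbid")

    label: str = "scenario"
    horizon: int = 10
    discount_rate: float = 0.015
    discount_rate_costs: Optional[float] = None
    perspective: str = "nhs_social_care"
    seed: int = 0
    catalogue: Optional[str] = None
    inputs: InputSpec = Field(default_factory=lambda: InputSpec(
        synthetic=SyntheticSpec()))
    interventions: list[InterventionSpec] = Field(default_factory=list)
    intervention_cost: float | list[float] = 0.0
    diseases: Optional[list[str]] = None
    include_unrelated_costs: bool = True
    productivity_stream: Optional[list[float]] = None
    wider_societal_stream: Optional[list[float]] = None
    options: OptionsSpec = Field(default_factory=OptionsSpec)

    def model_post_init(self, __context) -> None:
        if self.perspective not in PERSPECTIVES:
            raise ValueError(
                f"unknown perspective {self.perspective!r}; "
                f"choose from {sorted(PERSPECTIVES)}")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.diseases:
            unknown = set(self.diseases) - set(DISEASES)
            if unknown:
                raise ValueError(f"unknown diseases {sorted(unknown)}")
        if isinstance(self.intervention_cost, list) and (
                len(self.intervention_cost) > self.horizon):
            raise ValueError("intervention cost stream longer than horizon")


def load_config(path: str | Path | dict) -> ScenarioConfig:
    if isinstance(path, dict):
        data = path
    else:
        data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return ScenarioConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _load_inputs(cfg: ScenarioConfig):
    spec = cfg.inputs
    if spec.synthetic is not None:
        epi, mlt = synthetic_data.generate_baseline_epi(
            seed=spec.synthetic.seed, profile=spec.synthetic.profile)
        exposures = synthetic_data.generate_exposure_survey(
            seed=spec.synthetic.seed, ages=epi.ages, profile=spec.synthetic.profile)
        return epi, mlt, exposures
    if not (spec.baseline_epi and spec.life_table and spec.exposures):
        raise ConfigError(
            "inputs must give either `synthetic` or all of "
            "`baseline_epi`, `life_table`, `exposures`")
    epi = DiseaseEpi.from_frame(pd.read_csv(spec.baseline_epi))
    mlt = MainLifeTable.from_frame(pd.read_csv(spec.life_table))
    from .riskmodel import ExposureDistribution
    exposures = {}
    for f in sorted(Path(spec.exposures).glob("*.csv")):
        exposures[f.stem] = ExposureDistribution(f.stem, pd.read_csv(f))
    return epi, mlt, exposures


def execute_scenario(cfg: ScenarioConfig, seed: int | None = None) -> ScenarioResult:
    """Run the full pipeline for a parsed configuration."""
    ps = load_catalogue(cfg.catalogue)
    epi, mlt, exposures = _load_inputs(cfg)
    interventions = [
        Intervention(iv.risk_factor, iv.shift.type, iv.shift.amount, cfg.label)
        for iv in cfg.interventions
    ]
    return run_pipeline(
        ps, epi, mlt, exposures, interventions,
        horizon=cfg.horizon,
        discount_rate=cfg.discount_rate,
        discount_rate_costs=cfg.discount_rate_costs,
        perspective=cfg.perspective,
        intervention_cost=cfg.intervention_cost,
        diseases=cfg.diseases,
        include_unrelated=cfg.include_unrelated_costs,
        productivity=cfg.productivity_stream,
        wider_societal=cfg.wider_societal_stream,
        options=cfg.options.to_pipeline_options(),
        label=cfg.label,
    )


def write_bundle(result: ScenarioResult, cfg: ScenarioConfig,
                 out_dir: str | Path, seed: int) -> Path:
    """Write a self-describing result bundle: JSON summary, per-year CSV
    streams, the config snapshot, and the catalogue digest. Reproducible
    bit-identically from (config snapshot, digest, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ps = load_catalogue(cfg.catalogue)
    summary = {
        "label": result.label,
        "seed": seed,
        "settings": {
            "horizon": result.horizon,
            "discount_rate": result.discount_rate,
            "discount_rate_costs": result.discount_rate_costs,
            "perspective": result.perspective,
        },
        "econ": result.econ.to_dict(),
        "delta_cost_components": result.delta_cost_components(),
        "totals": {
            "qalys_baseline": result.qalys_baseline.total,
            "qalys_scenario": result.qalys_scenario.total,
            "life_years_baseline": result.traj_baseline.life_years,
            "life_years_scenario": result.traj_scenario.life_years,
        },
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    rows = []
    for which, cs, qs in (("baseline", result.costs_baseline, result.qalys_baseline),
                          ("scenario", result.costs_scenario, result.qalys_scenario)):
        comp = cs.components()
        for y in range(result.horizon):
            rows.append({
                "scenario": which, "year": y, "qalys": qs.qalys[y],
                **{k: v[y] for k, v in comp.items()},
            })
    pd.DataFrame(rows).to_csv(out / "streams.csv", index=False)
    (out / "config_snapshot.yaml").write_text(
        yaml.safe_dump(json.loads(cfg.model_dump_json()), sort_keys=True))
    (out / "catalogue_digest.json").write_text(
        json.dumps(ps.digest(), indent=2, sort_keys=True) + "\n")
    return out


#: Sensitivity-analysis variants executed by the harness.
SENSITIVITY_VARIANTS = (
    "horizon_1", "horizon_5", "horizon_20", "horizon_100",
    "nhs_only", "social_care_only", "with_productivity", "all_societal",
    "discount_3_5", "no_unrelated_costs", "no_cancer", "directly_related_only",
)

_DIET_FACTORS = {"fruit", "vegetables", "fibre", "fibre_cereal", "red_meat",
                 "processed_meat", "total_fat", "saturated_fat", "mufa",
                 "pufa", "dietary_cholesterol", "salt", "total_energy"}


def sensitivity_variants(cfg: ScenarioConfig) -> dict[str, ScenarioConfig]:
    """Build the variant configurations from a base scenario."""
    base = json.loads(cfg.model_dump_json())
    out: dict[str, ScenarioConfig] = {}

    def make(name: str, **over) -> None:
        data = json.loads(json.dumps(base))
        data.update(over)
        data["label"] = f"{cfg.label}__{name}"
        out[name] = ScenarioConfig(**data)

    for h in (1, 5, 20, 100):
        make(f"horizon_{h}", horizon=h,
             intervention_cost=_trim_cost(cfg.intervention_cost, h))
    make("nhs_only", perspective="nhs")
    make("social_care_only", perspective="social_care")
    horizon = cfg.horizon
    make("with_productivity", perspective="nhs_social_care_productivity",
         productivity_stream=cfg.productivity_stream or [0.0] * horizon)
    make("all_societal", perspective="all",
         productivity_stream=cfg.productivity_stream or [0.0] * horizon,
         wider_societal_stream=cfg.wider_societal_stream or [0.0] * horizon)
    make("discount_3_5", discount_rate=0.035, discount_rate_costs=0.035)
    make("no_unrelated_costs", include_unrelated_costs=False)
    make("no_cancer", diseases=["ihd", "stroke", "diabetes", "liver_cirrhosis"])
    touched = {iv.risk_factor for iv in cfg.interventions}
    related: set[str] = set()
    if touched & _DIET_FACTORS:
        related |= {"ihd", "stroke"}
    if "physical_activity" in touched:
        related |= {"ihd", "stroke", "diabetes", "breast_cancer",
                    "colorectal_cancer"}
    if not related:
        related = {"ihd", "stroke"}
    make("directly_related_only", diseases=sorted(related))
    return out


def _trim_cost(cost, horizon: int):
    if isinstance(cost, list):
        return cost[:horizon]
    return cost
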