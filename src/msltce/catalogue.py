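"""Parameter catalogue: relative risks, intermediate-pathway coefficients,
theoretical minimum exposures, mediation factors, utilities, and disease costs.

The catalogue ships as delimited-text tables (one CSV per source table) so it
can be audited line by line, and a JSON digest pins row counts and checksums.
All epidemiological and economic parameters used by the model are served from
here; nothing downstream hard-codes a parameter value.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DISEASES",
    "CANCERS",
    "RelativeRiskSpec",
    "IntermediateEffectSpec",
    "TheoreticalMinimum",
    "MediationSpec",
    "UtilityCatalogue",
    "CostCatalogue",
    "ParameterSet",
    "ValidationReport",
    "CatalogueError",
    "load_catalogue",
    "validate_catalogue",
    "parse_age_band",
]

#: Canonical names of the modelled diseases.
DISEASES = (
    "ihd",
    "stroke",
    "diabetes",
    "breast_cancer",
    "colorectal_cancer",
    "lung_cancer",
    "stomach_cancer",
    "liver_cancer",
    "kidney_cancer",
    "pancreatic_cancer",
    "liver_cirrhosis",
)

CANCERS = tuple(d for d in DISEASES if d.endswith("_cancer"))

#: Exposures (behavioural and intermediate) known to the catalogue.
RISK_FACTORS = (
    "fruit",
    "vegetables",
    "fibre",
    "fibre_cereal",
    "red_meat",
    "processed_meat",
    "total_fat",
    "saturated_fat",
    "mufa",
    "pufa",
    "dietary_cholesterol",
    "salt",
    "total_energy",
    "cholesterol",
    "sbp",
    "bmi",
    "diabetes",
    "physical_activity",
)

_TABLES = (
    "relative_risks",
    "intermediate_effects",
    "theoretical_minima",
    "mediation",
    "disease_costs",
    "baseline_utilities",
    "utility_decrements",
    "unrelated_costs_synthetic",
)

_AGE_MIN, _AGE_MAX = 0, 100


class CatalogueError(ValueError):
    """Raised when the catalogue cannot be loaded or a lookup fails."""


def parse_age_band(band: str | None) -> tuple[int, int]:
    """Parse an age-band string to a closed integer interval.

    ``"50-59"`` -> (50, 59); ``"<49"`` -> (0, 49); ``"80+"`` -> (80, 100);
    empty/None -> (0, 100).
    """
    if band is None or str(band).strip() == "" or (isinstance(band, float) and np.isnan(band)):
        return (_AGE_MIN, _AGE_MAX)
    s = str(band).strip()
    try:
        if s.startswith("<"):
            return (_AGE_MIN, int(s[1:]))
        if s.endswith("+"):
            return (int(s[:-1]), _AGE_MAX)
        lo, hi = s.split("-")
        return (int(lo), int(hi))
    except Exception as exc:  # pragma: no cover - defensive
        raise CatalogueError(f"malformed age band {band!r}") from exc


def _parse_range(band: str | None) -> tuple[float, float] | None:
    if band is None or str(band).strip() == "":
        return None
    lo, hi = str(band).split("-")
    return (float(lo), float(hi))


@dataclass(frozen=True)
class RelativeRiskSpec:
    """One relative-risk (or dose-response beta) entry.

    ``form`` is one of ``rr_per_unit`` (RR per ``unit_value`` of exposure),
    ``beta_quarter_power`` (beta of the quarter-power physical-activity
    transformation) or ``rr_binary`` (RR of disease given a binary condition,
    used for the diabetes -> cardiovascular coupling).
    """

    risk_factor: str
    disease: str
    unit_value: float | None
    unit_label: str
    value: float
    se: float
    distribution: str
    form: str = "rr_per_unit"
    sex: str | None = None
    age_band: tuple[int, int] = (_AGE_MIN, _AGE_MAX)
    exposure_band: tuple[float, float] | None = None

    def matches(self, sex: str | None = None, age: int | None = None) -> bool:
        if self.sex and sex and self.sex != sex:
            return False
        if age is not None and not (self.age_band[0] <= age <= self.age_band[1]):
            return False
        return True


@dataclass(frozen=True)
class IntermediateEffectSpec:
    risk_factor: str
    intermediate: str  # cholesterol | sbp | bmi
    unit_value: float
    unit_label: str
    coefficient: float | None
    se: float | None
    distribution: str = "normal"
    notes: str = ""


@dataclass(frozen=True)
class TheoreticalMinimum:
    risk_factor: str
    value: float
    se: float
    unit_label: str
    distribution: str = "normal"


@dataclass(frozen=True)
class MediationSpec:
    disease: str
    exposure: str
    intermediate: str
    unit_value: float
    unit_label: str
    coefficient: float
    se: float


class UtilityCatalogue:
    """Baseline EQ-5D utility by single year of age and sex, plus per-disease
    utility decrements (optionally split incident vs prevalent)."""

    def __init__(self, baseline: pd.DataFrame, decrements: pd.DataFrame):
        self._baseline = baseline.set_index("age") if "age" in baseline.columns else baseline
        self._base = {
            "male": self._baseline["male"].to_numpy(float),
            "female": self._baseline["female"].to_numpy(float),
        }
        self._dec: dict[str, dict[str, tuple[float, float]]] = {}
        for row in decrements.itertuples(index=False):
            self._dec.setdefault(row.disease, {})[row.phase] = (float(row.value), float(row.se))

    def baseline(self, age: int | np.ndarray, sex: str) -> float | np.ndarray:
        arr = self._base[sex]
        idx = np.clip(np.asarray(age, dtype=int), _AGE_MIN, _AGE_MAX)
        out = arr[idx]
        return float(out) if np.isscalar(age) or np.ndim(age) == 0 else out

    def decrement(self, disease: str, phase: str = "prevalent") -> float:
        try:
            phases = self._dec[disease]
        except KeyError:
            raise CatalogueError(f"no utility decrement for disease {disease!r}")
        if phase in phases:
            return phases[phase][0]
        if "all" in phases:
            return phases["all"][0]
        raise CatalogueError(f"no {phase!r} utility decrement for {disease!r}")

    def decrement_se(self, disease: str, phase: str = "prevalent") -> float:
        phases = self._dec[disease]
        key = phase if phase in phases else "all"
        return phases[key][1]

    def has_incident_split(self, disease: str) -> bool:
        return "incident" in self._dec.get(disease, {})

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(self._dec)

    def with_decrement(self, disease: str, value: float, phase: str = "all") -> "UtilityCatalogue":
        """Copy with one decrement replaced (used by sensitivity analyses)."""
        new = UtilityCatalogue.__new__(UtilityCatalogue)
        new._baseline = self._baseline
        new._base = self._base
        new._dec = {d: dict(p) for d, p in self._dec.items()}
        se = new._dec.get(disease, {}).get(phase, (0.0, 0.0))[1]
        new._dec.setdefault(disease, {})[phase] = (value, se)
        return new


class CostCatalogue:
    """Per-disease NHS costs, per-person unrelated-disease spend by age/sex,
    and the social-care unit cost applied from ``min_social_care_age``."""

    def __init__(
        self,
        disease_costs: pd.DataFrame,
        unrelated: pd.DataFrame,
        social_care_monthly: float = 4826.0,
        min_social_care_age: int = 75,
    ):
        self.disease_costs = disease_costs.set_index("disease")
        piv = unrelated.pivot(index="age", columns="sex", values="annual_cost")
        self._unrelated = {s: piv[s].to_numpy(float) for s in ("male", "female")}
        self.social_care_monthly = float(social_care_monthly)
        self.min_social_care_age = int(min_social_care_age)

    def per_case(self, disease: str) -> float:
        try:
            return float(self.disease_costs.loc[disease, "cost_per_prevalent_case"])
        except KeyError:
            raise CatalogueError(f"no cost entry for disease {disease!r}")

    def components(self, disease: str) -> tuple[float, float, float]:
        row = self.disease_costs.loc[disease]
        return tuple(
            float(row[c]) if pd.notna(row[c]) else 0.0
            for c in ("programme_budgeting_k", "specialised_services_k", "primary_care_k")
        )

    def total_disease_cost(self, disease: str) -> float:
        return float(self.disease_costs.loc[disease, "total_k"])

    def unrelated(self, age: int | np.ndarray, sex: str) -> float | np.ndarray:
        arr = self._unrelated[sex]
        idx = np.clip(np.asarray(age, dtype=int), _AGE_MIN, _AGE_MAX)
        out = arr[idx]
        return float(out) if np.ndim(age) == 0 else out


@dataclass
class ValidationReport:
    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, msg: str) -> None:
        self.findings.append(msg)

    def __iter__(self):
        return iter(self.findings)

    def __len__(self):
        return len(self.findings)


def _data_dir() -> Path:
    return Path(resources.files("msltce").joinpath("data"))


def _read_table(source: Path, name: str) -> pd.DataFrame:
    path = source / f"{name}.csv"
    if not path.exists():
        raise CatalogueError(f"catalogue table {name!r} not found at {path}")
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise CatalogueError(f"catalogue table {name!r} is malformed: {exc}") from exc


def _num(df: pd.DataFrame, cols: Iterable[str], table: str, allow_blank: Iterable[str] = ()) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        blank = out[c].astype(str).str.strip() == ""
        vals = pd.to_numeric(out[c].where(~blank, other=np.nan), errors="coerce")
        bad = vals.isna() & ~blank
        if bad.any():
            raise CatalogueError(
                f"malformed numeric in table {table!r} column {c!r}: "
                f"{out.loc[bad, c].iloc[0]!r}"
            )
        if blank.any() and c not in allow_blank:
            raise CatalogueError(f"missing value in table {table!r} column {c!r}")
        out[c] = vals
    return out


class ParameterSet:
    """The loaded catalogue. Raw text frames are retained so that
    ``save(load(x))`` is lossless; typed accessors serve parsed values."""

    def __init__(self, raw: Mapping[str, pd.DataFrame], source: Path):
        self.raw = dict(raw)
        self.source = Path(source)
        self._parse()

    # -- parsing -----------------------------------------------------------
    def _parse(self) -> None:
        rr = _num(
            self.raw["relative_risks"],
            ["unit_value", "value", "se"],
            "relative_risks",
            allow_blank=["unit_value"],
        )
        self.relative_risks: list[RelativeRiskSpec] = [
            RelativeRiskSpec(
                risk_factor=r.risk_factor,
                disease=r.disease,
                unit_value=None if pd.isna(r.unit_value) else float(r.unit_value),
                unit_label=r.unit_label,
                value=float(r.value),
                se=float(r.se),
                distribution=r.distribution,
                form=r.form,
                sex=r.sex or None,
                age_band=parse_age_band(r.age_band),
                exposure_band=_parse_range(r.exposure_band),
            )
            for r in rr.itertuples(index=False)
        ]
        ie = _num(
            self.raw["intermediate_effects"],
            ["unit_value", "coefficient", "se"],
            "intermediate_effects",
            allow_blank=["coefficient", "se"],
        )
        self.intermediate_effects: dict[str, IntermediateEffectSpec] = {
            r.risk_factor: IntermediateEffectSpec(
                risk_factor=r.risk_factor,
                intermediate=r.intermediate,
                unit_value=float(r.unit_value),
                unit_label=r.unit_label,
                coefficient=None if pd.isna(r.coefficient) else float(r.coefficient),
                se=None if pd.isna(r.se) else float(r.se),
                distribution=r.distribution,
                notes=r.notes,
            )
            for r in ie.itertuples(index=False)
        }
        tm = _num(self.raw["theoretical_minima"], ["value", "se"], "theoretical_minima")
        self.theoretical_minima: dict[str, TheoreticalMinimum] = {
            r.risk_factor: TheoreticalMinimum(
                r.risk_factor, float(r.value), float(r.se), r.unit_label, r.distribution
            )
            for r in tm.itertuples(index=False)
        }
        md = _num(self.raw["mediation"], ["unit_value", "coefficient", "se"], "mediation")
        self.mediations: list[MediationSpec] = [
            MediationSpec(
                r.disease, r.exposure, r.intermediate,
                float(r.unit_value), r.unit_label, float(r.coefficient), float(r.se),
            )
            for r in md.itertuples(index=False)
        ]
        ut = _num(self.raw["baseline_utilities"], ["age", "male", "female"], "baseline_utilities")
        dec = _num(self.raw["utility_decrements"], ["value", "se"], "utility_decrements")
        self.utilities = UtilityCatalogue(ut, dec)
        dc = _num(
            self.raw["disease_costs"],
            ["programme_budgeting_k", "specialised_services_k", "primary_care_k",
             "total_k", "cost_per_prevalent_case"],
            "disease_costs",
            allow_blank=["specialised_services_k", "primary_care_k"],
        )
        unrel = _num(self.raw["unrelated_costs_synthetic"], ["age", "annual_cost"],
                     "unrelated_costs_synthetic")
        self.costs = CostCatalogue(dc, unrel)

    # -- lookups -----------------------------------------------------------
    def rr_entries(self, risk_factor: str, disease: str | None = None) -> list[RelativeRiskSpec]:
        out = [r for r in self.relative_risks if r.risk_factor == risk_factor]
        if disease is not None:
            out = [r for r in out if r.disease == disease]
        return out

    def rr(self, risk_factor: str, disease: str, sex: str | None = None,
           age: int | None = None) -> RelativeRiskSpec:
        cands = [r for r in self.rr_entries(risk_factor, disease) if r.matches(sex, age)]
        if not cands:
            raise CatalogueError(
                f"no relative risk for {risk_factor!r} -> {disease!r} (sex={sex}, age={age})"
            )
        if len(cands) > 1 and all(c.exposure_band for c in cands):
            return cands[0]  # exposure-banded; caller uses rr_entries
        return cands[0]

    def tmin(self, risk_factor: str) -> TheoreticalMinimum:
        try:
            return self.theoretical_minima[risk_factor]
        except KeyError:
            raise CatalogueError(f"no theoretical minimum for {risk_factor!r}")

    def intermediate_effect(self, risk_factor: str) -> IntermediateEffectSpec:
        try:
            return self.intermediate_effects[risk_factor]
        except KeyError:
            raise CatalogueError(f"no intermediate-pathway coefficient for {risk_factor!r}")

    def mediation(self, disease: str, exposure: str, intermediate: str) -> MediationSpec:
        for m in self.mediations:
            if (m.disease, m.exposure, m.intermediate) == (disease, exposure, intermediate):
                return m
        raise CatalogueError(
            f"no mediation factor for ({disease!r}, {exposure!r}, {intermediate!r})"
        )

    def mediations_for(self, disease: str, exposure: str) -> list[MediationSpec]:
        return [m for m in self.mediations if m.disease == disease and m.exposure == exposure]

    # -- persistence -------------------------------------------------------
    def save(self, target: str | Path) -> None:
        target = Path(target)
        target.mkdir(parents=True, exist_ok=True)
        for name, df in self.raw.items():
            df.to_csv(target / f"{name}.csv", index=False)
        digest = {}
        for name in sorted(self.raw):
            text = (target / f"{name}.csv").read_text()
            digest[f"{name}.csv"] = {
                "rows": len(self.raw[name]),
                "sha256": hashlib.sha256(text.encode()).hexdigest(),
            }
        (target / "digest.json").write_text(json.dumps(digest, indent=2, sort_keys=True) + "\n")

    def digest(self) -> dict:
        out = {}
        for name in sorted(self.raw):
            path = self.source / f"{name}.csv"
            text = path.read_text()
            out[f"{name}.csv"] = {
                "rows": len(self.raw[name]),
                "sha256": hashlib.sha256(text.encode()).hexdigest(),
            }
        return out


def load_catalogue(source: str | Path | None = None) -> ParameterSet:
    """Load the parameter catalogue from ``source`` (a directory of CSV
    tables) or, by default, the packaged catalogue."""
    src = Path(source) if source is not None else _data_dir()
    raw = {name: _read_table(src, name) for name in _TABLES}
    return ParameterSet(raw, src)


def validate_catalogue(ps: ParameterSet) -> ValidationReport:
    """Check every catalogue invariant; findings are reported, not raised."""
    rep = ValidationReport()
    for r in ps.relative_risks:
        if r.form == "rr_per_unit" and r.value <= 0:
            rep.add(f"relative risk must be positive: {r.risk_factor}->{r.disease} = {r.value}")
        if r.se < 0:
            rep.add(f"negative SE: {r.risk_factor}->{r.disease}")
        if r.risk_factor not in RISK_FACTORS:
            rep.add(f"unknown risk factor {r.risk_factor!r}")
        if r.disease not in DISEASES:
            rep.add(f"unknown disease {r.disease!r}")
    # overlapping age bands within (risk_factor, disease, sex, exposure_band)
    groups: dict[tuple, list[RelativeRiskSpec]] = {}
    for r in ps.relative_risks:
        if r.age_band != (_AGE_MIN, _AGE_MAX) or True:
            groups.setdefault((r.risk_factor, r.disease, r.sex, r.exposure_band), []).append(r)
    for key, specs in groups.items():
        if len(specs) < 2:
            continue
        bands = sorted(s.age_band for s in specs)
        for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
            if lo2 <= hi1 and not all(s.exposure_band for s in specs):
                rep.add(f"overlapping age bands {bands} for {key[0]}->{key[1]}")
                break
    for t in ps.theoretical_minima.values():
        if t.se < 0:
            rep.add(f"negative SE on theoretical minimum {t.risk_factor}")
        if t.unit_label in ("g/day",) and t.value < 0:
            rep.add(f"negative theoretical minimum intake {t.risk_factor}")
    allowed_triples = {(m.disease, m.exposure, m.intermediate) for m in ps.mediations}
    for m in ps.mediations:
        if m.disease not in ("ihd", "stroke"):
            rep.add(f"mediation for unsupported disease {m.disease!r}")
    del allowed_triples
    base = ps.utilities._baseline
    for sex in ("male", "female"):
        vals = base[sex].to_numpy(float)
        if (vals < 0).any() or (vals > 1).any():
            rep.add(f"baseline utility out of [0,1] for sex {sex}")
        if (np.diff(vals) > 1e-12).any():
            rep.add(f"baseline utility not non-increasing with age for sex {sex}")
    for d in ps.utilities.diseases:
        for phase in ("incident", "prevalent", "all"):
            try:
                v = ps.utilities._dec[d][phase][0]
            except KeyError:
                continue
            if v > 0:
                rep.add(f"utility decrement positive for {d}/{phase}")
    dc = ps.costs.disease_costs
    for col in ("programme_budgeting_k", "specialised_services_k", "primary_care_k",
                "total_k", "cost_per_prevalent_case"):
        neg = dc[col].astype(float) < 0
        if neg.any():
            rep.add(f"negative cost component {col} for {list(dc.index[neg.fillna(False)])}")
    if ps.costs.social_care_monthly < 0:
        rep.add("negative social care monthly cost")
    return rep
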