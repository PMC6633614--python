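"""Cost streams, discounting, and cost-effectiveness / return-on-investment.

Cost components per simulated year:

* modelled-disease health costs: prevalent cases times the annual cost per
  prevalent case from the programme-budgeting-derived catalogue;
* unrelated-disease health costs: person-years alive times an age/sex annual
  spend profile (so longer survival accrues more unrelated spend);
* social care from age 75: persons times 12 monthly payments of the unit
  residential-care cost, scaled by a need function increasing in (1 - utility);
* intervention costs, and optional pass-through productivity / wider-societal
  streams for sensitivity analyses.

The headline statistics follow the standard decision-analytic definitions:
ICER = (C_b - C_a)/(E_b - E_a) with dominance classification, and for
cost-saving interventions ROI = money saved per pound spent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .catalogue import CostCatalogue, UtilityCatalogue
from .lifetable import CohortTrajectory
from .outcomes import utility_array

__all__ = [
    "CostStream",
    "EconResult",
    "PERSPECTIVES",
    "aggregate_disease_cost",
    "health_costs",
    "social_care_costs",
    "default_need_function",
    "discount",
    "cost_effectiveness",
    "return_on_investment",
    "build_cost_stream",
]

#: Perspective name -> cost components included (intervention cost always in).
PERSPECTIVES = {
    "nhs": ("modelled", "unrelated", "intervention"),
    "social_care": ("social_care", "intervention"),
    "nhs_social_care": ("modelled", "unrelated", "social_care", "intervention"),
    "nhs_social_care_productivity": (
        "modelled", "unrelated", "social_care", "productivity", "intervention"),
    "all": ("modelled", "unrelated", "social_care", "productivity",
            "wider_societal", "intervention"),
}


@dataclass
class CostStream:
    """Per-year cost components (GBP) for one scenario."""

    label: str
    modelled: np.ndarray
    unrelated: np.ndarray
    social_care: np.ndarray
    intervention: np.ndarray
    productivity: np.ndarray = field(default=None)  # type: ignore[assignment]
    wider_societal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.modelled)
        if self.productivity is None:
            self.productivity = np.zeros(n)
        if self.wider_societal is None:
            self.wider_societal = np.zeros(n)
        for name in ("modelled", "unrelated", "social_care", "intervention"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"negative {name} cost")

    def components(self) -> dict[str, np.ndarray]:
        return {
            "modelled": self.modelled,
            "unrelated": self.unrelated,
            "social_care": self.social_care,
            "productivity": self.productivity,
            "wider_societal": self.wider_societal,
            "intervention": self.intervention,
        }

    def total(self, perspective: str = "nhs_social_care",
              include_unrelated: bool = True) -> np.ndarray:
        try:
            parts = PERSPECTIVES[perspective]
        except KeyError:
            raise ValueError(f"unknown perspective {perspective!r}")
        comp = self.components()
        out = np.zeros_like(self.modelled)
        for p in parts:
            if p == "unrelated" and not include_unrelated:
                continue
            out = out + comp[p]
        return out


@dataclass
class EconResult:
    """Discounted incremental costs and effects with the derived statistics.

    ``delta_cost`` is C_b - C_a (intervention minus no-intervention) and
    ``delta_qalys`` is E_b - E_a. ``classification`` is ``icer`` when the
    quotient is meaningful, ``dominant`` (cheaper and better), ``dominated``
    (dearer and worse), or ``undefined`` when the QALY difference is zero."""

    delta_cost: float
    delta_qalys: float
    classification: str
    icer: float | None
    roi: float | None
    roi_signed: float | None
    perspective: str
    horizon: int
    discount_rate: float

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "classification": self.classification,
            "icer": self.icer,
            "roi": self.roi,
            "roi_signed": self.roi_signed,
            "perspective": self.perspective,
            "horizon": self.horizon,
            "discount_rate": self.discount_rate,
        }


def aggregate_disease_cost(
    programme_budgeting: float, specialised: float, primary_care: float
) -> float:
    """Total NHS disease cost (thousands GBP) as the exact sum of the
    programme-budgeting, specialised-services and primary-care components."""
    parts = (programme_budgeting, specialised, primary_care)
    if any(p < 0 for p in parts):
        raise ValueError("negative cost component")
    return float(sum(parts))


def health_costs(
    traj: CohortTrajectory, cc: CostCatalogue
) -> tuple[np.ndarray, np.ndarray]:
    """(modelled, unrelated) health costs per simulated year.

    Modelled: prevalent persons per disease times the annual cost per
    prevalent case. Unrelated: person-years alive times the age/sex annual
    spend on diseases outside the model."""
    H = traj.horizon
    modelled = np.zeros(H)
    unrelated = np.zeros(H)
    per_case = {d: cc.per_case(d) for d in traj.diseases}
    for y in range(H):
        for d in traj.diseases:
            modelled[y] += float(
                (traj.prevalence[d][:, :, y] * traj.person_years[:, :, y]).sum()
            ) * per_case[d]
        ages = np.clip(traj.attained_ages(y), 0, 100)
        for si, sex in enumerate(("male", "female")):
            unrelated[y] += float(
                (traj.person_years[si, :, y] * cc.unrelated(ages, sex)).sum()
            )
    return modelled, unrelated


def default_need_function(age: np.ndarray, utility: np.ndarray) -> np.ndarray:
    """Share of the full residential-care unit cost needed at a given
    quality of life: the utility shortfall (1 - u), clipped to [0, 1].
    Increasing in lost quality of life, zero at full health."""
    return np.clip(1.0 - utility, 0.0, 1.0)


def social_care_costs(
    traj: CohortTrajectory,
    uc: UtilityCatalogue,
    cc: CostCatalogue,
    need_function: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Social-care costs per year: persons aged >= 75 times 12 monthly unit
    costs, weighted by the (replaceable) need function of age and utility."""
    g = need_function or default_need_function
    u = utility_array(traj, uc)
    H = traj.horizon
    out = np.zeros(H)
    annual_unit = 12.0 * cc.social_care_monthly
    for y in range(H):
        ages = traj.attained_ages(y)
        eligible = ages >= cc.min_social_care_age
        if not eligible.any():
            continue
        for si in range(2):
            persons = traj.person_years[si, eligible, y]
            need = g(ages[eligible], u[si, eligible, y])
            out[y] += float((persons * need).sum()) * annual_unit
    return out


def discount(stream: Sequence[float] | np.ndarray, rate: float) -> float:
    """Present value with the first model year undiscounted:
    PV = sum_y v_y / (1 + rate)^y, y = 0, 1, ..."""
    if rate < -1:
        raise ValueError("discount rate below -100%")
    v = np.asarray(stream, dtype=float)
    factors = (1.0 + rate) ** (-np.arange(len(v)))
    return float((v * factors).sum())


def cost_effectiveness(
    c_b: float, c_a: float, e_b: float, e_a: float,
    perspective: str = "nhs_social_care",
    horizon: int = 10,
    discount_rate: float = 0.015,
    c_i: float = 0.0,
) -> EconResult:
    """Incremental cost-effectiveness of the intervention (b) versus no
    intervention (a), all inputs discounted over the same horizon."""
    dc = c_b - c_a
    de = e_b - e_a
    icer: float | None = None
    roi = roi_signed = None
    if de == 0:
        classification = "undefined"
    elif dc < 0 and de > 0:
        classification = "dominant"
        icer = dc / de
    elif dc > 0 and de < 0:
        classification = "dominated"
        icer = dc / de
    else:
        classification = "icer"
        icer = dc / de
    if dc < 0 and c_i > 0:
        roi, roi_signed = return_on_investment(c_b, c_a, c_i)
    return EconResult(
        delta_cost=dc, delta_qalys=de, classification=classification,
        icer=icer, roi=roi, roi_signed=roi_signed,
        perspective=perspective, horizon=horizon, discount_rate=discount_rate,
    )


def return_on_investment(c_b: float, c_a: float, c_i: float) -> tuple[float, float]:
    """Money saved per pound of intervention spend, for cost-saving
    interventions only. Returns (magnitude, signed quotient); the raw signed
    value (C_b - C_a)/C_i is negative when cost-saving and is preserved
    alongside the reported magnitude."""
    if c_i == 0:
        raise ValueError("intervention cost is zero; ROI undefined")
    dc = c_b - c_a
    if dc >= 0:
        raise ValueError("not cost-saving; ROI not reported")
    signed = dc / c_i
    return abs(signed), signed


def build_cost_stream(
    traj: CohortTrajectory,
    uc: UtilityCatalogue,
    cc: CostCatalogue,
    intervention_cost: Sequence[float] | float = 0.0,
    productivity: Sequence[float] | None = None,
    wider_societal: Sequence[float] | None = None,
    need_function: Callable | None = None,
) -> CostStream:
    """Assemble the full cost stream for one trajectory."""
    H = traj.horizon
    modelled, unrelated = health_costs(traj, cc)
    social = social_care_costs(traj, uc, cc, need_function)
    iv = np.asarray(intervention_cost, dtype=float)
    if iv.ndim == 0:
        iv = np.r_[float(iv), np.zeros(H - 1)] if H > 0 else np.zeros(0)
    elif len(iv) < H:
        iv = np.r_[iv, np.zeros(H - len(iv))]
    elif len(iv) > H:
        raise ValueError("intervention cost stream longer than horizon")
    prod = np.asarray(productivity, float) if productivity is not None else np.zeros(H)
    wider = np.asarray(wider_societal, float) if wider_societal is not None else np.zeros(H)
    return CostStream(
        label=traj.label, modelled=modelled, unrelated=unrelated,
        social_care=social, intervention=iv,
        productivity=prod, wider_societal=wider,
    )
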