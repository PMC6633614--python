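"""Utility-weighted person-years (QALYs).

Population utility at an attained age is the baseline EQ-5D value for that
age and sex plus additive per-disease decrements weighted by prevalence.
Decrements combine additively across co-prevalent diseases with no
interaction term, and the result is floored at zero. Where a disease has
separate incident and prevalent decrements, the newly incident fraction of
the cohort receives the incident value in its first year (toggleable)."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .catalogue import UtilityCatalogue
from .lifetable import CohortTrajectory

__all__ = ["QALYStream", "population_utility", "utility_array", "qaly_stream"]


@dataclass
class QALYStream:
    label: str
    qalys: np.ndarray  # per simulated year, undiscounted

    @property
    def total(self) -> float:
        return float(self.qalys.sum())


def population_utility(
    age: int,
    sex: str,
    disease_prevalences: Mapping[str, float],
    uc: UtilityCatalogue,
) -> float:
    """Mean utility at one age/sex given prevalent disease proportions."""
    u = uc.baseline(age, sex)
    for disease, prev in disease_prevalences.items():
        if not 0.0 <= prev <= 1.0:
            raise ValueError(f"prevalence outside [0,1] for {disease}")
        u += prev * uc.decrement(disease, "prevalent")
    return max(u, 0.0)


def utility_array(
    traj: CohortTrajectory,
    uc: UtilityCatalogue,
    incident_decrement: bool = True,
) -> np.ndarray:
    """Mean utility per (sex, cohort, year), following cohorts down the
    baseline utility table as they age."""
    n_s, n_c, H = traj.person_years.shape
    out = np.zeros((n_s, n_c, H))
    for y in range(H):
        ages = np.clip(traj.attained_ages(y), 0, 100)
        for si, sex in enumerate(("male", "female")):
            u = np.asarray(uc.baseline(ages, sex), dtype=float).copy()
            for d in traj.diseases:
                dec_prev = uc.decrement(d, "prevalent")
                prev = traj.prevalence[d][si, :, y]
                u += prev * dec_prev
                if incident_decrement and uc.has_incident_split(d):
                    newc = traj.new_cases[d][si, :, y]
                    u += newc * (uc.decrement(d, "incident") - dec_prev)
            out[si, :, y] = np.maximum(u, 0.0)
    active = traj.person_years > 0
    return np.where(active, out, 0.0)


def qaly_stream(
    traj: CohortTrajectory,
    uc: UtilityCatalogue,
    incident_decrement: bool = True,
) -> QALYStream:
    """Yearly QALYs: person-years times mean utility, summed over age and sex."""
    u = utility_array(traj, uc, incident_decrement)
    yearly = (u * traj.person_years).sum(axis=(0, 1))
    return QALYStream(label=traj.label, qalys=yearly)
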