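"""Monte Carlo probabilistic sensitivity analysis (PSA).

Every uncertain catalogue parameter is resampled per run: relative risks are
lognormal with the median pinned at the point estimate; dose-response betas,
theoretical minima, intermediate-pathway and mediation coefficients, and
utility decrements are normal; health and societal cost multipliers are gamma
with mean 1 and SD 0.1. Age-banded relative risks of one exposure-disease
pair share a single z-score by default (fully correlated bands).

Sampling uses counter-based substreams keyed by (seed, run, stable hash of
the parameter id), so adding a parameter to the catalogue never reshuffles
the draws of the others, and any draw is reproducible from (seed, index).
Uncertainty intervals are the empirical 2.5th and 97.5th percentiles over
runs (default 2000, by which point they are stable)."""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .catalogue import ParameterSet, UtilityCatalogue

__all__ = [
    "DEFAULT_N_RUNS",
    "ParameterDraw",
    "PSASummary",
    "sample_parameters",
    "apply_draw",
    "run_psa",
]

DEFAULT_N_RUNS = 2000

_GAMMA_SHAPE = 1.0 / 0.1**2  # mean 1, SD 0.1
_GAMMA_SCALE = 0.1**2


def _substream(seed: int, index: int, key: str) -> np.random.Generator:
    h = int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big")
    return np.random.default_rng([int(seed), int(index), h])


def _z(seed: int, index: int, key: str) -> float:
    return float(_substream(seed, index, key).standard_normal())


@dataclass(frozen=True)
class ParameterDraw:
    """One sampled realisation of every uncertain parameter."""

    seed: int
    index: int
    values: Mapping[str, float]

    @property
    def health_cost_multiplier(self) -> float:
        return self.values["cost_mult:health"]

    @property
    def societal_cost_multiplier(self) -> float:
        return self.values["cost_mult:societal"]


@dataclass
class PSASummary:
    """Point estimate and 95% uncertainty interval per output."""

    outputs: dict[str, dict]
    n_runs: int
    n_failed: int = 0
    runs: dict[str, np.ndarray] = field(default_factory=dict)


def _rr_key(r) -> str:
    return (f"rr:{r.risk_factor}:{r.disease}:{r.sex or 'both'}:"
            f"{r.age_band[0]}-{r.age_band[1]}:{r.exposure_band}")


def _rr_group_key(r) -> str:
    return f"rrgrp:{r.risk_factor}:{r.disease}:{r.sex or 'both'}"


def sample_parameters(
    ps: ParameterSet,
    seed: int,
    index: int,
    correlated_age_bands: bool = True,
) -> ParameterDraw:
    """Draw one realisation of the catalogue's uncertain parameters.

    Lognormal RRs use sigma = SE/value (delta method on the log scale) so
    the sample median equals the point estimate. Zero-SE parameters are
    returned at their point value."""
    values: dict[str, float] = {}
    for r in ps.relative_risks:
        key = _rr_key(r)
        if r.se == 0:
            values[key] = r.value
            continue
        if r.distribution == "lognormal":
            zkey = _rr_group_key(r) if correlated_age_bands else key
            z = _z(seed, index, zkey)
            sigma = r.se / r.value
            values[key] = float(np.exp(np.log(r.value) + sigma * z))
        else:  # normal (quarter-power betas)
            values[key] = r.value + r.se * _z(seed, index, key)
    for f, spec in ps.intermediate_effects.items():
        if spec.coefficient is None:
            continue
        if spec.se is None:
            raise ValueError(f"missing SE for intermediate effect {f!r}")
        values[f"ie:{f}"] = spec.coefficient + spec.se * _z(seed, index, f"ie:{f}")
    for f, tm in ps.theoretical_minima.items():
        values[f"tmin:{f}"] = tm.value + tm.se * _z(seed, index, f"tmin:{f}")
        if tm.unit_label == "g/day":
            values[f"tmin:{f}"] = max(values[f"tmin:{f}"], 0.0)
    for m in ps.mediations:
        key = f"med:{m.disease}:{m.exposure}:{m.intermediate}"
        values[key] = m.coefficient + m.se * _z(seed, index, key)
    uc = ps.utilities
    for d in uc.diseases:
        for phase in ("incident", "prevalent", "all"):
            try:
                v, se = uc._dec[d][phase]
            except KeyError:
                continue
            key = f"udec:{d}:{phase}"
            values[key] = v + se * _z(seed, index, key) if se else v
    for which in ("health", "societal"):
        key = f"cost_mult:{which}"
        rng = _substream(seed, index, key)
        values[key] = float(rng.gamma(_GAMMA_SHAPE, _GAMMA_SCALE))
    return ParameterDraw(seed=seed, index=index, values=dict(values))


def apply_draw(ps: ParameterSet, draw: ParameterDraw) -> ParameterSet:
    """Clone the parameter set with sampled values substituted.

    The raw text tables are shared (they describe the point catalogue); only
    the parsed parameter objects are replaced. Cost multipliers are applied
    by the caller to the assembled cost streams, matching the generic
    multiplicative-uncertainty treatment of costs."""
    new = ParameterSet.__new__(ParameterSet)
    new.raw = ps.raw
    new.source = ps.source
    new.relative_risks = [
        replace(r, value=draw.values.get(_rr_key(r), r.value))
        for r in ps.relative_risks
    ]
    new.intermediate_effects = {
        f: (spec if spec.coefficient is None
            else replace(spec, coefficient=draw.values.get(f"ie:{f}", spec.coefficient)))
        for f, spec in ps.intermediate_effects.items()
    }
    new.theoretical_minima = {
        f: replace(tm, value=draw.values.get(f"tmin:{f}", tm.value))
        for f, tm in ps.theoretical_minima.items()
    }
    new.mediations = [
        replace(m, coefficient=draw.values.get(
            f"med:{m.disease}:{m.exposure}:{m.intermediate}", m.coefficient))
        for m in ps.mediations
    ]
    uc = ps.utilities
    new_uc = UtilityCatalogue.__new__(UtilityCatalogue)
    new_uc._baseline = uc._baseline
    new_uc._base = uc._base
    new_uc._dec = {
        d: {phase: (draw.values.get(f"udec:{d}:{phase}", v), se)
            for phase, (v, se) in phases.items()}
        for d, phases in uc._dec.items()
    }
    new.utilities = new_uc
    new.costs = ps.costs
    return new


def run_psa(
    model: Callable[[ParameterDraw], Mapping[str, float]],
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
    ps: ParameterSet | None = None,
    point: Mapping[str, float] | None = None,
    correlated_age_bands: bool = True,
) -> PSASummary:
    """Run ``model`` once per parameter draw and summarise the outputs.

    ``model`` receives a ParameterDraw and returns a mapping of output name
    to value (e.g. delta_cost, delta_qalys, icer). Failing runs are recorded
    and excluded. Percentiles use linear interpolation of the order
    statistics and are invariant to run order."""
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    if ps is None:
        from .catalogue import load_catalogue
        ps = load_catalogue()
    results: dict[str, list[float]] = {}
    n_failed = 0
    for i in range(n_runs):
        draw = sample_parameters(ps, seed, i, correlated_age_bands)
        try:
            out = model(draw)
        except Exception:
            n_failed += 1
            continue
        for k, v in out.items():
            results.setdefault(k, []).append(float(v) if v is not None else np.nan)
    outputs = {}
    runs = {}
    for k, vals in results.items():
        arr = np.asarray(vals, dtype=float)
        runs[k] = arr
        finite = arr[np.isfinite(arr)]
        lo, hi = (np.percentile(finite, [2.5, 97.5]) if len(finite)
                  else (np.nan, np.nan))
        outputs[k] = {
            "point": (None if point is None else point.get(k)),
            "lo": float(lo),
            "hi": float(hi),
            "mean": float(finite.mean()) if len(finite) else float("nan"),
        }
    return PSASummary(outputs=outputs, n_runs=n_runs, n_failed=n_failed, runs=runs)
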