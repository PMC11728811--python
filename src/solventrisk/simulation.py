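"""Monte Carlo propagation of exposure factors into hazard quotients/indices.

Each iteration simulates one worker: a shared daily exposure time ET
(hours/day), exposure duration ED (years) and exposure frequency EF
(days/year), plus an independent airborne concentration per chemical
(ppm).  The chronic exposure concentration is the time-weighted average

    EC = (C × ET × ED × EF) / (AT × 24)

with the averaging time AT in days (converted to hours in the
denominator), so EC keeps the units of C.  The hazard quotient is
HQ = EC / RfC per chemical, and the hazard index HI sums the HQs of the
chemicals sharing a target-organ toxicity (dose addition).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distfit import DistributionSpec
from .errors import ConfigurationError
from .reference_data import (
    MG_M3,
    MOLAR_VOLUME_L_PER_MOL,
    PPM,
    ChemicalSpec,
    ToxicityGrouping,
    convert_concentration,
    resolve_reference_concentration,
)

__all__ = [
    "DEFAULT_AT_DAYS",
    "DEFAULT_ITERATIONS",
    "PERCENTILE_GRID",
    "ExposureFactorModel",
    "FactorDraws",
    "SimulationResult",
    "sample_factors",
    "compute_ec",
    "compute_hq",
    "compute_hi",
    "evaluate_draws",
    "run_simulation",
    "exceedance_percentile",
    "summarize_percentiles",
    "scenario_hash",
]

DEFAULT_AT_DAYS = 69_408.0
DEFAULT_ITERATIONS = 10_000
PERCENTILE_GRID = (25.0, 50.0, 75.0, 95.0)
_HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class ExposureFactorModel:
    """Joint specification of the exposure factors.

    ``concentration_specs`` are in ppm; ``et_spec`` hours/day; ``ed_spec``
    years; ``ef_spec`` days/year; ``at_days`` is the fixed averaging time
    in days.
    """

    concentration_specs: Mapping[str, DistributionSpec]
    et_spec: DistributionSpec
    ed_spec: DistributionSpec
    ef_spec: DistributionSpec
    at_days: float = DEFAULT_AT_DAYS

    def __post_init__(self) -> None:
        if not self.at_days > 0:
            raise ConfigurationError(f"at_days must be positive, got {self.at_days}")


@dataclass(frozen=True)
class FactorDraws:
    """Per-iteration factor draws: one simulated worker per row."""

    n: int
    seed: int | None
    et: np.ndarray
    ed: np.ndarray
    ef: np.ndarray
    concentrations: dict  # chemical name -> ppm draws, length n

    def as_frame(self) -> pd.DataFrame:
        cols = {"et_hours_per_day": self.et, "ed_years": self.ed, "ef_days_per_year": self.ef}
        for name, c in self.concentrations.items():
            cols[f"conc_ppm:{name}"] = c
        return pd.DataFrame(cols)


def _draw_positive(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n positive variates, resampling any draw ≤ 0.

    A spec rejecting more than half of its proposals is treated as
    misconfigured (the intended factors are essentially never negative).
    """
    x = spec.sample(n, rng)
    proposed = n
    rejected = int(np.count_nonzero(x <= 0))
    while True:
        bad = x <= 0
        nbad = int(bad.sum())
        if nbad == 0:
            return x
        if rejected > 0.5 * proposed:
            raise ConfigurationError(
                f"{spec.family} spec rejects >50% of proposals at zero-truncation "
                f"({rejected}/{proposed}); check its parameters"
            )
        x[bad] = spec.sample(nbad, rng)
        proposed += nbad
        rejected += int(np.count_nonzero(x[bad] <= 0))


def sample_factors(
    model: ExposureFactorModel,
    n: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
) -> FactorDraws:
    """Draw the factor matrix for ``n`` iterations, reproducibly under ``seed``.

    ET, ED and EF are drawn once per iteration and shared across chemicals;
    concentrations are drawn independently per chemical, in the model's
    chemical order.  All draws are truncated to (0, ∞) by resampling.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    et = _draw_positive(model.et_spec, n, rng)
    ed = _draw_positive(model.ed_spec, n, rng)
    ef = _draw_positive(model.ef_spec, n, rng)
    conc = {name: _draw_positive(spec, n, rng) for name, spec in model.concentration_specs.items()}
    return FactorDraws(n=n, seed=seed, et=et, ed=ed, ef=ef, concentrations=conc)


def compute_ec(c, et, ed, ef, at_days: float):
    """Exposure concentration: (C × ET × ED × EF) / (AT_days × 24).

    Vectorized; the result carries the units of ``c``.
    """
    if not at_days > 0:
        raise ConfigurationError(f"at_days must be positive, got {at_days}")
    return (c * et * ed * ef) / (at_days * _HOURS_PER_DAY)


def compute_hq(ec, rfc: float):
    """Hazard quotient EC/RfC; > 1 flags unacceptable non-carcinogenic risk."""
    if not rfc > 0:
        raise ConfigurationError(f"RfC must be positive, got {rfc}")
    return ec / rfc


def compute_hi(hq_by_chemical: Mapping[str, float | np.ndarray], grouping: ToxicityGrouping):
    """Hazard index: sum of member HQs (dose addition within a target organ)."""
    missing = [m for m in grouping.members if m not in hq_by_chemical]
    if missing:
        raise ConfigurationError(
            f"group {grouping.group_name!r}: missing HQ for member(s) {missing}"
        )
    total = hq_by_chemical[grouping.members[0]]
    for m in grouping.members[1:]:
        total = total + hq_by_chemical[m]
    return total


def exceedance_percentile(samples, threshold: float = 1.0) -> float:
    """Percentile of the empirical distribution at which ``threshold`` is reached.

    Returns 100 × fraction(samples ≤ threshold); ties at the threshold count
    as non-exceeding.  Its complement is the percent of draws above the
    threshold.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ConfigurationError("need at least one sample")
    return 100.0 * np.count_nonzero(x <= threshold) / x.size


def summarize_percentiles(samples, grid: Sequence[float] = PERCENTILE_GRID) -> dict:
    """Empirical percentiles on ``grid`` (linear interpolation between order stats)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ConfigurationError("need at least one sample")
    vals = np.percentile(x, list(grid))
    return {float(q): float(v) for q, v in zip(grid, vals)}


@dataclass(frozen=True)
class SimulationResult:
    """HQ/HI draws with summaries and provenance.

    ``hq`` is an (n × chemicals) DataFrame, ``hi`` an (n × groups)
    DataFrame whose columns are elementwise sums of the member HQ columns.
    """

    hq: pd.DataFrame
    hi: pd.DataFrame
    draws: FactorDraws
    groupings: tuple[ToxicityGrouping, ...]
    rfc_by_chemical: dict
    seed: int | None
    n: int
    model_hash: str
    percentile_grid: tuple[float, ...] = PERCENTILE_GRID

    @property
    def provenance(self) -> dict:
        return {"seed": self.seed, "n": self.n, "model_hash": self.model_hash}

    def _summary(self, frame: pd.DataFrame) -> pd.DataFrame:
        rows = {}
        for col in frame.columns:
            x = frame[col].to_numpy()
            row = {f"p{g:g}": v for g, v in summarize_percentiles(x, self.percentile_grid).items()}
            row["percent_above_1"] = 100.0 - exceedance_percentile(x, 1.0)
            row["exceedance_percentile"] = exceedance_percentile(x, 1.0)
            rows[col] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def hq_summary(self) -> pd.DataFrame:
        """Per-chemical percentiles of HQ plus the percent of draws above 1."""
        return self._summary(self.hq)

    def hi_summary(self) -> pd.DataFrame:
        """Per-group percentiles of HI plus the percent of draws above 1."""
        return self._summary(self.hi)


def scenario_hash(
    chems: Sequence[ChemicalSpec],
    model: ExposureFactorModel,
    groupings: Sequence[ToxicityGrouping],
) -> str:
    """Stable digest of the scenario, used to tie results to reports."""
    blob = json.dumps(
        {
            "chemicals": [
                [c.name, c.molecular_weight, dict(c.rfc_by_toxicity), dict(c.rfd_by_toxicity)]
                for c in chems
            ],
            "factors": {
                "conc": {k: [s.family, sorted(s.params.items())] for k, s in model.concentration_specs.items()},
                "et": [model.et_spec.family, sorted(model.et_spec.params.items())],
                "ed": [model.ed_spec.family, sorted(model.ed_spec.params.items())],
                "ef": [model.ef_spec.family, sorted(model.ef_spec.params.items())],
                "at_days": model.at_days,
            },
            "groupings": {g.group_name: list(g.members) for g in groupings},
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _toxicity_label(chem: ChemicalSpec, groupings: Sequence[ToxicityGrouping]) -> str:
    labels = [g.group_name for g in groupings if chem.name in g.members]
    if not labels:
        raise ConfigurationError(f"chemical {chem.name!r} belongs to no toxicity group")
    if len(labels) > 1:
        raise ConfigurationError(f"chemical {chem.name!r} appears in several groups: {labels}")
    return labels[0]


def evaluate_draws(
    chems: Sequence[ChemicalSpec],
    draws: FactorDraws,
    groupings: Sequence[ToxicityGrouping],
    at_days: float = DEFAULT_AT_DAYS,
    molar_volume: float = MOLAR_VOLUME_L_PER_MOL,
    model_hash: str = "",
) -> SimulationResult:
    """Turn factor draws into HQ and HI draws.

    Concentrations are converted from ppm to mg/m³ before division by the
    RfC resolved for each chemical's toxicity group.
    """
    chem_by_name = {c.name: c for c in chems}
    hq_cols: dict[str, np.ndarray] = {}
    rfc_by_chem: dict[str, float] = {}
    for grouping in groupings:
        for member in grouping.members:
            if member not in chem_by_name:
                raise ConfigurationError(
                    f"group {grouping.group_name!r} names unknown chemical {member!r}"
                )
    for name, c_ppm in draws.concentrations.items():
        if name not in chem_by_name:
            continue
        chem = chem_by_name[name]
        label = _toxicity_label(chem, groupings)
        rfc = resolve_reference_concentration(chem, label)
        c_mgm3 = convert_concentration(c_ppm, chem.molecular_weight, PPM, MG_M3, molar_volume)
        ec = compute_ec(c_mgm3, draws.et, draws.ed, draws.ef, at_days)
        hq_cols[name] = compute_hq(ec, rfc)
        rfc_by_chem[name] = rfc
    hq = pd.DataFrame(hq_cols)
    hi = pd.DataFrame({g.group_name: compute_hi(hq_cols, g) for g in groupings})
    return SimulationResult(
        hq=hq,
        hi=hi,
        draws=draws,
        groupings=tuple(groupings),
        rfc_by_chemical=rfc_by_chem,
        seed=draws.seed,
        n=draws.n,
        model_hash=model_hash,
    )


def run_simulation(
    chems: Sequence[ChemicalSpec],
    model: ExposureFactorModel,
    groupings: Sequence[ToxicityGrouping],
    n: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    molar_volume: float = MOLAR_VOLUME_L_PER_MOL,
) -> SimulationResult:
    """Full Monte Carlo run: sample factors, propagate to HQ/HI, summarize."""
    for grouping in groupings:
        for member in grouping.members:
            if member not in model.concentration_specs:
                raise ConfigurationError(
                    f"group {grouping.group_name!r}: no concentration spec for {member!r}"
                )
    draws = sample_factors(model, n, seed)
    return evaluate_draws(
        chems,
        draws,
        groupings,
        at_days=model.at_days,
        molar_volume=molar_volume,
        model_hash=scenario_hash(chems, model, groupings),
    )
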