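"""Synthetic workplace-monitoring records and worker-factor samples.

The real Korean workplace monitoring records behind the default scenario
are not public, so this module generates record tables with the same
statistical structure: per-chemical log-normal airborne concentrations
(ppm) at the published per-chemical sample sizes, plus worker-factor
tables drawn from the exposure-factor model.  Every output is a pure
function of (configuration, seed).

Metadata fields (business/industry/process codes) use stable synthetic
vocabularies; they carry no information and exist only so downstream code
sees realistically shaped records.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .distfit import DistributionSpec
from .errors import ConfigurationError
from .reference_data import ChemicalSpec
from .simulation import ExposureFactorModel, _draw_positive

__all__ = [
    "MEASUREMENT_COLUMNS",
    "generate_measurements",
    "generate_measurement_table",
    "generate_worker_factors",
]

#: Fixed column order of the measurement CSV.
MEASUREMENT_COLUMNS = (
    "year",
    "business_id",
    "industry_code",
    "process_code",
    "worker_id",
    "chemical",
    "concentration_ppm",
)

_INDUSTRY_CODE = "C31111"  # steel shipbuilding
_PROCESS_CODES = ("P-PAINT-01", "P-PAINT-02", "P-PAINT-03")
_N_BUSINESSES = 13  # shipbuilding companies in the source statistics

_CONCENTRATION_FAMILIES = frozenset({"lognormal", "exponential", "gamma", "weibull", "point_mass"})


def generate_measurements(
    chem: ChemicalSpec,
    spec: DistributionSpec,
    n: int,
    seed: int | None = None,
    year: int = 2018,
) -> pd.DataFrame:
    """Generate ``n`` monitoring records for one chemical.

    Concentrations are drawn from ``spec`` (must be supported on the
    positive reals); metadata fields come from deterministic synthetic
    vocabularies.  Reproducible under ``seed``.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if spec.family not in _CONCENTRATION_FAMILIES:
        raise ConfigurationError(
            f"family {spec.family!r} is not supported on positive reals; "
            f"cannot model concentrations"
        )
    if spec.family == "point_mass" and not spec.params["value"] > 0:
        raise ConfigurationError("point-mass concentration must be positive")
    rng = np.random.default_rng(seed)
    conc = _draw_positive(spec, n, rng)
    business = rng.integers(0, _N_BUSINESSES, n)
    process = rng.integers(0, len(_PROCESS_CODES), n)
    return pd.DataFrame(
        {
            "year": np.full(n, year),
            "business_id": [f"B{1000 + b}" for b in business],
            "industry_code": np.full(n, _INDUSTRY_CODE),
            "process_code": [_PROCESS_CODES[p] for p in process],
            "worker_id": [f"W{seed if seed is not None else 0}-{i:05d}" for i in range(n)],
            "chemical": np.full(n, chem.name),
            "concentration_ppm": conc,
        },
        columns=list(MEASUREMENT_COLUMNS),
    )


def generate_measurement_table(
    chems: Sequence[ChemicalSpec],
    concentration_specs: dict,
    seed: int | None = None,
    counts: dict | None = None,
    year: int = 2018,
) -> pd.DataFrame:
    """Generate the full multi-chemical record table.

    Per-chemical counts default to each chemical's
    ``record_count_default``; chemicals are emitted in the given order and
    records are independent across chemicals (no within-worker coupling).
    """
    frames = []
    for i, chem in enumerate(chems):
        n = (counts or {}).get(chem.name, chem.record_count_default)
        if n < 1:
            raise ConfigurationError(f"{chem.name}: record count must be >= 1, got {n}")
        if chem.name not in concentration_specs:
            raise ConfigurationError(f"{chem.name}: no concentration spec")
        sub_seed = None if seed is None else (seed * 1000 + i) % (2**31)
        frames.append(
            generate_measurements(chem, concentration_specs[chem.name], n, sub_seed, year)
        )
    return pd.concat(frames, ignore_index=True)


def generate_worker_factors(
    model: ExposureFactorModel,
    n: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample ``n`` workers' (ET, ED, EF) rows from the factor model.

    Suitable for distribution-fitting round trips; all values positive.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "et_hours_per_day": _draw_positive(model.et_spec, n, rng),
            "ed_years": _draw_positive(model.ed_spec, n, rng),
            "ef_days_per_year": _draw_positive(model.ef_spec, n, rng),
        }
    )
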