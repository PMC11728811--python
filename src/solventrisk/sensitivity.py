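"""Spearman rank-correlation sensitivity of HQ/HI outputs to input factors.

Each report row correlates one input factor (a chemical's airborne
concentration, or the shared exposure duration/time/frequency) against an
output draw vector, and labels the coefficient with a strength band on
|ρ|: negligible < 0.20 ≤ low < 0.40 ≤ moderate < 0.70 ≤ high < 0.90 ≤
very high ≤ 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UndefinedCoefficientError
from .reference_data import ToxicityGrouping
from .simulation import FactorDraws, SimulationResult

__all__ = [
    "STRENGTH_BANDS",
    "SensitivityReport",
    "spearman_rho",
    "categorize_strength",
    "sensitivity_report",
    "hq_sensitivity",
    "hi_sensitivity",
]

#: (upper bound on |ρ|, category); intervals half-open, top band closed at 1.
STRENGTH_BANDS = (
    (0.20, "negligible"),
    (0.40, "low"),
    (0.70, "moderate"),
    (0.90, "high"),
    (1.0, "very high"),
)

FACTOR_ED = "exposure_duration"
FACTOR_ET = "daily_exposure_time"
FACTOR_EF = "exposure_frequency"


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mean ranks).

    Without ties the exact rank-difference identity
    ρ = 1 − 6·Σd² / (n(n²−1)) is used, so perfectly monotone inputs give
    exactly ±1; with ties the coefficient is the Pearson correlation of
    mean ranks (scipy), clipped to [−1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("inputs must be 1-D vectors of equal length")
    if x.size < 3:
        raise ConfigurationError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCoefficientError("rank correlation undefined for constant input")
    ties = np.unique(x).size != x.size or np.unique(y).size != y.size
    if not ties:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        d2 = float(np.sum((rx - ry) ** 2))  # integer-valued, exact below 2^53
        n = x.size
        return 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    rho = float(stats.spearmanr(x, y).statistic)
    return min(1.0, max(-1.0, rho))


def categorize_strength(rho: float) -> str:
    """Map |ρ| to its strength band."""
    a = abs(rho)
    if a > 1:
        raise ConfigurationError(f"|rho| must be <= 1, got {rho}")
    for upper, label in STRENGTH_BANDS:
        if a < upper:
            return label
    return STRENGTH_BANDS[-1][1]  # |rho| == 1


@dataclass(frozen=True)
class SensitivityReport:
    """Spearman coefficients of each input factor against one output."""

    output_label: str
    table: pd.DataFrame  # index: factor name; columns: rho, strength
    n: int
    seed: int | None
    model_hash: str = ""

    @property
    def provenance(self) -> dict:
        return {"seed": self.seed, "n": self.n, "model_hash": self.model_hash}


def sensitivity_report(
    draws: FactorDraws,
    output: Sequence[float],
    label: str,
    chemicals: Sequence[str] | None = None,
    model_hash: str = "",
) -> SensitivityReport:
    """Correlate the factor draws against one output vector.

    ``chemicals`` restricts which concentration columns appear: for the HQ
    of one chemical pass that chemical alone; for an HI pass the group
    members.  Defaults to every chemical in the draws.
    """
    y = np.asarray(output, dtype=float)
    if y.size != draws.n:
        raise ConfigurationError(
            f"output length {y.size} does not match iteration count {draws.n}"
        )
    if chemicals is None:
        chemicals = list(draws.concentrations)
    rows = {}
    for name in chemicals:
        if name not in draws.concentrations:
            raise ConfigurationError(f"no concentration draws for chemical {name!r}")
        rows[f"concentration:{name}"] = draws.concentrations[name]
    rows[FACTOR_ED] = draws.ed
    rows[FACTOR_ET] = draws.et
    rows[FACTOR_EF] = draws.ef
    records = {}
    for factor, x in rows.items():
        rho = spearman_rho(x, y)
        records[factor] = {"rho": rho, "strength": categorize_strength(rho)}
    table = pd.DataFrame.from_dict(records, orient="index")
    return SensitivityReport(label, table, draws.n, draws.seed, model_hash)


def hq_sensitivity(result: SimulationResult, chemical: str) -> SensitivityReport:
    """Sensitivity of one chemical's HQ to its own concentration and the shared factors."""
    if chemical not in result.hq.columns:
        raise ConfigurationError(f"no HQ draws for chemical {chemical!r}")
    return sensitivity_report(
        result.draws,
        result.hq[chemical].to_numpy(),
        f"HQ:{chemical}",
        chemicals=[chemical],
        model_hash=result.model_hash,
    )


def hi_sensitivity(result: SimulationResult, grouping: ToxicityGrouping) -> SensitivityReport:
    """Sensitivity of a group HI to every member concentration and the shared factors."""
    if grouping.group_name not in result.hi.columns:
        raise ConfigurationError(f"no HI draws for group {grouping.group_name!r}")
    return sensitivity_report(
        result.draws,
        result.hi[grouping.group_name].to_numpy(),
        f"HI:{grouping.group_name}",
        chemicals=list(grouping.members),
        model_hash=result.model_hash,
    )
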