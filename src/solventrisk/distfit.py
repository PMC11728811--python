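"""Parametric models for exposure factors: moment matching and AIC selection.

Exposure factors are described by univariate parametric families.  Two
routes produce a :class:`DistributionSpec`:

* :func:`moments_to_spec` — closed-form moment matching when only a
  published arithmetic mean and standard deviation are available;
* :func:`fit_mle` / :func:`select_by_aic` — maximum-likelihood fitting of
  raw samples with Akaike-Information-Criterion family selection
  (AIC = 2k − 2·logL, minimized).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import ConfigurationError, DataError

__all__ = [
    "FAMILIES",
    "DEFAULT_CANDIDATES",
    "DistributionSpec",
    "FitRow",
    "FitRanking",
    "moments_to_spec",
    "fit_mle",
    "select_by_aic",
]

FAMILIES = ("lognormal", "logistic", "exponential", "normal", "gamma", "weibull", "point_mass")

#: Families tried by default when selecting from raw samples.
DEFAULT_CANDIDATES = ("normal", "lognormal", "logistic", "exponential", "gamma", "weibull")

#: Families whose support is the positive reals.
_POSITIVE_SUPPORT = frozenset({"lognormal", "exponential", "gamma", "weibull"})

#: Free-parameter count per family (for AIC).
_N_PARAMS = {
    "normal": 2,
    "lognormal": 2,
    "logistic": 2,
    "exponential": 1,
    "gamma": 2,
    "weibull": 2,
}


@dataclass(frozen=True)
class DistributionSpec:
    """One univariate parametric distribution with provenance.

    ``mean``/``sd`` record the arithmetic summary the spec represents: the
    matched survey statistics for ``source="moment_matched"`` (the printed
    SD is kept as metadata even for one-parameter families), or the
    analytic moments of the fitted parameters for ``source="mle_fitted"``.
    """

    family: str
    params: dict
    source: str = "moment_matched"
    mean: float = float("nan")
    sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        p = self.params
        try:
            if self.family == "lognormal":
                _require(p["sigma"] > 0, "lognormal sigma must be > 0")
            elif self.family == "logistic":
                _require(p["scale"] > 0, "logistic scale must be > 0")
            elif self.family == "exponential":
                _require(p["rate"] > 0, "exponential rate must be > 0")
            elif self.family == "normal":
                _require(p["scale"] > 0, "normal scale must be > 0")
            elif self.family in ("gamma", "weibull"):
                _require(p["shape"] > 0 and p["scale"] > 0, f"{self.family} shape/scale must be > 0")
        except KeyError as exc:
            raise ConfigurationError(f"{self.family}: missing parameter {exc.args[0]!r}") from None

    # -- analytic moments ------------------------------------------------

    def analytic_mean(self) -> float:
        f, p = self.family, self.params
        if f == "lognormal":
            return math.exp(p["mu"] + p["sigma"] ** 2 / 2)
        if f == "logistic":
            return p["loc"]
        if f == "exponential":
            return 1.0 / p["rate"]
        if f == "normal":
            return p["loc"]
        if f == "gamma":
            return p["shape"] * p["scale"]
        if f == "weibull":
            return p["scale"] * special.gamma(1 + 1 / p["shape"])
        return p["value"]  # point_mass

    def analytic_sd(self) -> float:
        f, p = self.family, self.params
        if f == "lognormal":
            s2 = p["sigma"] ** 2
            return math.exp(p["mu"] + s2 / 2) * math.sqrt(math.expm1(s2))
        if f == "logistic":
            return p["scale"] * math.pi / math.sqrt(3.0)
        if f == "exponential":
            return 1.0 / p["rate"]
        if f == "normal":
            return p["scale"]
        if f == "gamma":
            return math.sqrt(p["shape"]) * p["scale"]
        if f == "weibull":
            k, lam = p["shape"], p["scale"]
            g1 = special.gamma(1 + 1 / k)
            g2 = special.gamma(1 + 2 / k)
            return lam * math.sqrt(max(g2 - g1 * g1, 0.0))
        return 0.0  # point_mass

    # -- sampling and likelihood -----------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` variates; consumes the generator stream deterministically."""
        f, p = self.family, self.params
        if f == "lognormal":
            return np.exp(p["mu"] + p["sigma"] * rng.standard_normal(n))
        if f == "logistic":
            return p["loc"] + p["scale"] * rng.logistic(0.0, 1.0, n)
        if f == "exponential":
            return rng.exponential(1.0 / p["rate"], n)
        if f == "normal":
            return p["loc"] + p["scale"] * rng.standard_normal(n)
        if f == "gamma":
            return rng.gamma(p["shape"], p["scale"], n)
        if f == "weibull":
            return p["scale"] * rng.weibull(p["shape"], n)
        return np.full(n, float(p["value"]))  # point_mass

    def frozen(self):
        """The equivalent ``scipy.stats`` frozen distribution."""
        f, p = self.family, self.params
        if f == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))
        if f == "logistic":
            return stats.logistic(loc=p["loc"], scale=p["scale"])
        if f == "exponential":
            return stats.expon(scale=1.0 / p["rate"])
        if f == "normal":
            return stats.norm(loc=p["loc"], scale=p["scale"])
        if f == "gamma":
            return stats.gamma(a=p["shape"], scale=p["scale"])
        if f == "weibull":
            return stats.weibull_min(c=p["shape"], scale=p["scale"])
        raise ConfigurationError("point_mass has no scipy equivalent")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


# ---------------------------------------------------------------------------
# moment matching
# ---------------------------------------------------------------------------

def _weibull_shape_from_cv(cv: float) -> float:
    """Solve Γ(1+2/k)/Γ(1+1/k)² − 1 = cv² for the Weibull shape k."""

    def f(k: float) -> float:
        g1 = special.gammaln(1 + 1 / k)
        g2 = special.gammaln(1 + 2 / k)
        return math.expm1(g2 - 2 * g1) - cv * cv

    return optimize.brentq(f, 0.05, 200.0, xtol=1e-12, rtol=1e-14)


def moments_to_spec(family: str, mean: float, sd: float) -> DistributionSpec:
    """Parameterize ``family`` so its analytic mean/SD match the arguments.

    ``sd = 0`` degenerates to a point mass at ``mean`` for every family.
    For the one-parameter exponential only the mean is matched (rate =
    1/mean); the supplied SD is retained as summary metadata.
    """
    if sd < 0:
        raise ConfigurationError(f"sd must be nonnegative, got {sd}")
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}")
    if family in _POSITIVE_SUPPORT and not mean > 0:
        raise ConfigurationError(f"{family}: mean must be positive, got {mean}")
    if sd == 0 or family == "point_mass":
        return DistributionSpec("point_mass", {"value": mean}, "fixed", mean, 0.0)

    if family == "lognormal":
        s2 = math.log1p((sd / mean) ** 2)
        params = {"mu": math.log(mean) - s2 / 2, "sigma": math.sqrt(s2)}
    elif family == "logistic":
        params = {"loc": mean, "scale": sd * math.sqrt(3.0) / math.pi}
    elif family == "exponential":
        params = {"rate": 1.0 / mean}
    elif family == "normal":
        params = {"loc": mean, "scale": sd}
    elif family == "gamma":
        params = {"shape": (mean / sd) ** 2, "scale": sd * sd / mean}
    else:  # weibull
        k = _weibull_shape_from_cv(sd / mean)
        params = {"shape": k, "scale": mean / special.gamma(1 + 1 / k)}
    return DistributionSpec(family, params, "moment_matched", mean, sd)


# ---------------------------------------------------------------------------
# maximum likelihood and AIC selection
# ---------------------------------------------------------------------------

def _check_samples(samples: np.ndarray, family: str) -> None:
    if samples.size < 10:
        raise DataError(f"need at least 10 samples to fit, got {samples.size}")
    if family in _POSITIVE_SUPPORT:
        bad = np.flatnonzero(samples <= 0)
        if bad.size:
            raise DataError(
                f"{family}: support is positive reals; offending rows {bad[:10].tolist()}"
                + (" ..." if bad.size > 10 else "")
            )
    if np.ptp(samples) == 0:
        raise DataError(f"{family}: samples are all equal; scale is degenerate")


def fit_mle(samples: Sequence[float], family: str) -> tuple[DistributionSpec, float]:
    """Maximum-likelihood fit of one family; returns (spec, log-likelihood).

    Closed forms are used for normal, lognormal and exponential; logistic,
    gamma and Weibull use scipy's deterministic numeric optimizer (started
    from the data moments, tolerance 1e-8).
    """
    x = np.asarray(samples, dtype=float)
    if family not in _N_PARAMS:
        raise ConfigurationError(f"cannot fit family {family!r}")
    _check_samples(x, family)

    if family == "normal":
        params = {"loc": float(x.mean()), "scale": float(x.std())}
    elif family == "lognormal":
        lx = np.log(x)
        params = {"mu": float(lx.mean()), "sigma": float(lx.std())}
    elif family == "exponential":
        params = {"rate": float(1.0 / x.mean())}
    elif family == "logistic":
        loc, scale = stats.logistic.fit(x)
        params = {"loc": float(loc), "scale": float(scale)}
    elif family == "gamma":
        a, _, scale = stats.gamma.fit(x, floc=0)
        params = {"shape": float(a), "scale": float(scale)}
    else:  # weibull
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        params = {"shape": float(c), "scale": float(scale)}

    spec = DistributionSpec(family, params, "mle_fitted")
    spec = DistributionSpec(family, params, "mle_fitted", spec.analytic_mean(), spec.analytic_sd())
    loglik = float(spec.frozen().logpdf(x).sum())
    return spec, loglik


@dataclass(frozen=True)
class FitRow:
    family: str
    loglik: float
    k: int
    aic: float
    spec: DistributionSpec


@dataclass(frozen=True)
class FitRanking:
    """Per-family AIC table with the selected (minimum-AIC) family."""

    rows: tuple[FitRow, ...]
    selected: str
    inapplicable: dict = field(default_factory=dict)

    @property
    def selected_spec(self) -> DistributionSpec:
        return next(r.spec for r in self.rows if r.family == self.selected)


def select_by_aic(
    samples: Sequence[float],
    candidate_families: Iterable[str] = DEFAULT_CANDIDATES,
) -> FitRanking:
    """Fit every applicable candidate family and select the minimum AIC.

    Families whose support excludes the data are reported as inapplicable
    rather than raising.  Ties are broken by fewest parameters, then by
    family name; the result is invariant to candidate order.
    """
    x = np.asarray(samples, dtype=float)
    candidates = list(dict.fromkeys(candidate_families))
    if not candidates:
        raise DataError("no candidate families given")
    rows: list[FitRow] = []
    inapplicable: dict[str, str] = {}
    for family in candidates:
        try:
            spec, loglik = fit_mle(x, family)
        except DataError as exc:
            inapplicable[family] = str(exc)
            continue
        k = _N_PARAMS[family]
        aic = 2.0 * k - 2.0 * loglik
        if not math.isfinite(aic):
            inapplicable[family] = "non-finite AIC"
            continue
        rows.append(FitRow(family, loglik, k, aic, spec))
    if not rows:
        raise DataError(f"no applicable family among {candidates}")
    rows.sort(key=lambda r: (r.aic, r.k, r.family))
    return FitRanking(tuple(rows), rows[0].family, inapplicable)
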