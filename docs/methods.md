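# Methods

## Model and assumptions

The package screens chronic non-carcinogenic inhalation risk for a
population of workers exposed to a mixture of organic solvents. One Monte
Carlo iteration represents one worker. The worker draws a daily exposure
time ET (hours/day), an exposure duration ED (years) and an exposure
frequency EF (days/year) once, shared across all chemicals; each
chemical's airborne concentration C (ppm) is drawn independently. This
encodes two assumptions: work patterns are a property of the worker, not
of the chemical, and between-chemical concentration correlation is not
modelled (measurement records are treated as independent per chemical).

The chronic exposure concentration is the time-weighted average

    EC = (C × ET × ED × EF) / (AT × 24)

where AT is a fixed averaging time in days and the factor 24 expresses it
in hours, so EC keeps the units of C. The hazard quotient is HQ = EC/RfC
after converting C to mg/m³; the hazard index for a target-organ group is
the dose-addition sum HI = Σ HQ over members. HQ and HI above 1 flag
unacceptable risk; the headline summary for a distribution of draws is the
percentile at which it crosses 1 (100 × fraction of draws ≤ 1), whose
complement is the percent of workers above 1.

## Parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| ET | logistic, mean 8, SD 1.11 | h/day | survey of daily workplace exposure time |
| ED | exponential, mean 11 | years | survey of years in the job; one-parameter family, so only the mean is matched and the surveyed SD (8.69) is kept as metadata |
| EF | lognormal, mean 268, SD 20.92 | days/year | survey of annual working days |
| AT | 69,408 (fixed) | days | averaging-time constant of the source configuration, used verbatim |
| C (per chemical) | lognormal, moment-matched | ppm | monitoring-program arithmetic mean ± SD per chemical |
| molar volume | 24.45 | L/mol | 25 °C / 1 atm convention for ppm ↔ mg/m³; configurable |
| body weight / inhalation volume | 70 kg / 20 m³/day | — | RfD → RfC conversion defaults |
| iterations | 10,000 | — | standard for stable percentile and rank-correlation estimates (Monte Carlo SE on a crossing percentile ≈ 0.5 points) |

The source survey lists ET as "hours/week" and EF as "days/week" with
values 8 and 268, which is not internally consistent; the package adopts
ET in hours/day and EF in days/year. This is the only reading under which
hand-computed median HQs land near the published ones, and it is fixed
throughout, not configurable per-factor.

Reference values: a directly published RfC always takes precedence over a
converted RfD for the same toxicity label; the conversion exists only to
fill gaps. Extra published endpoints (hepatic, urinary, "other") are
stored in the chemical registry but excluded from the two default
target-organ groups.

## Distribution handling

Moment matching is closed-form per family: lognormal
σ² = ln(1 + (sd/mean)²), μ = ln mean − σ²/2; logistic scale = sd·√3/π;
gamma shape = (mean/sd)², scale = sd²/mean; Weibull shape solved from the
coefficient of variation by Brent's method (bracket 0.05–200, xtol 1e-12);
exponential rate = 1/mean. sd = 0 degenerates to a point mass for every
family. Fitting raw samples uses maximum likelihood — closed forms for
normal, lognormal and exponential, scipy's deterministic optimizer for
logistic, gamma and Weibull (location fixed at 0 for the positive
families) — and families are ranked by AIC = 2k − 2·logL, ties broken by
fewest parameters then family name, so candidate order never matters.
Families whose support excludes the data (e.g. lognormal with a
non-positive sample) are reported as inapplicable rather than failing the
ranking. Note that gamma and Weibull both contain the exponential at
shape 1, so with all six candidate families an exponential sample is
occasionally claimed by a two-parameter neighbour despite the AIC penalty;
family-recovery checks therefore use the four-family candidate set
{normal, lognormal, exponential, logistic}, which is also the set of
shapes the survey factors actually take.

## Numerical conventions

- Sampling: one `numpy` Generator seeded per run; draw order is fixed
  (ET, ED, EF, then chemicals in model order), so equal seeds give
  bit-identical draws. Lognormal draws are exp(μ + σZ) with Z standard
  normal, which makes scaling a chemical's mean and SD by k scale its HQ
  draws by k to machine precision.
- Truncation: every factor is resampled until positive; a specification
  that rejects more than half of its proposals is treated as
  misconfigured and raises. At the default logistic ET the rejection rate
  is ~1e-10 per draw.
- Quantiles: linear interpolation between order statistics
  (`numpy.percentile` default). Ties at the threshold count as
  non-exceeding (the crossing percentile uses ≤).
- Spearman ρ: with no ties the exact identity 1 − 6Σd²/(n(n²−1)) on
  integer ranks (so ρ(x, x) = 1 exactly and monotone transforms leave ρ
  exactly unchanged); with ties, Pearson correlation of mean ranks via
  scipy, clipped to [−1, 1]. Strength bands are applied to |ρ| as
  half-open intervals [0, 0.2), [0.2, 0.4), [0.4, 0.7), [0.7, 0.9),
  [0.9, 1]; the published band edges ("0–0.19, 0.20–0.39, …") leave
  (0.19, 0.20) undefined, and the half-open reading closes those gaps.
- Sensitivity is computed on the same draw matrix as the simulation (no
  resampling), so reported coefficients describe exactly the run that
  produced the HQ/HI tables; reports carry the run's seed, iteration
  count and a scenario hash, and the renderer refuses to mix runs.

## Synthetic data

The generator emulates workplace-monitoring record tables: per-chemical
lognormal concentrations at the published per-chemical sample sizes
(952/449/868/172/427/290, total 3,158), plus metadata columns (year,
business, industry, process, worker codes) drawn from small stable
synthetic vocabularies, and worker-factor tables drawn from the factor
model. Everything is a pure function of (configuration, seed). It does
not emulate: heavier-than-lognormal tails, non-detects or detection
limits, the twice-yearly sampling calendar, within-worker correlation
across chemicals, or process-level differences (spray vs brush). Tests
passing on synthetic data therefore demonstrate the pipeline's
correctness and the statistical identifiability of the assumed families —
not that real monitoring data follow those families.

## Design choices

- Moment matching is the default concentration route because only summary
  statistics of the original records are public. Its known consequence is
  light tails: when the real records are heavier-tailed than lognormal, a
  lognormal fitted to raw data has larger log-σ than one moment-matched
  to the arithmetic mean/SD, and upper percentiles (95th-percentile HQs,
  HI crossing percentiles for groups dominated by tail draws) are
  understated. Median-level quantities are insensitive to this.
- AT is used verbatim as a fixed constant without lifetime
  interpretation.
- The scenario file is YAML with wholesale replacement for the chemical
  list and key-wise merging for factors; an empty file is exactly the
  packaged default scenario.
- Tables are CSV at 4 significant digits with provenance headers
  (`# seed=…`, `# iterations=…`, `# model_hash=…`); logs go to stderr,
  results never do.

## Problem sizes

The default run is 10,000 iterations × 6 chemicals (fractions of a second
on one CPU). Statistical tests use 5,000-sample fits, 100-seed
family-recovery loops, a 100,000-draw moment check and a 40,000-draw
discrete-enumeration oracle; the whole suite runs in a few seconds.

## Known limitations

Inhalation route only; no dermal or ingestion exposure, no carcinogenic
slope-factor risk, no time-varying exposure within a workday, no
censored-data handling, and no variance-based (Sobol) sensitivity —
Spearman rank correlation only, which captures monotone association but
not interactions.
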