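# Methods

This note documents the statistical models, numerical choices and design
decisions behind `wqbench`, and what the synthetic benchmark does and
does not show about real monitoring data.

## Synthetic populations

High-frequency TRP records from agricultural catchments are strictly
positive, right-skewed and often bimodal: a "baseflow" mode around
0.01–0.05 mg P L⁻¹ and a heavier "storm" mode at higher concentrations.
The generator draws i.i.d. values from one- or two-component parametric
mixtures (lognormal, gamma or Weibull components) by inverse-CDF
sampling on two uniform streams — one stream selects the component, one
the value — which makes a degenerate two-component spec with weights
(1, 0) bit-identical to the single-component spec under the same seed.

**Temporal structure is deliberately absent.** Sub-sampling is uniform
with replacement and unconstrained in time, so serial correlation,
seasonality and storm hydrographs would not change any quantity computed
here; timestamps are cosmetic. Consequently the benchmark says nothing
about calendar-stratified or flow-weighted sampling designs, and passing
tests on these populations does not certify performance on records whose
sampling interacts with temporal structure.

Optional left-censoring replaces values below the analyser detection
limit (0.003 mg P L⁻¹) by the limit (substitution, not truncation),
mimicking reported instrument behaviour. It is off by default.

Three registered presets fix the study conditions (the source study
reports no fitted mixture parameters, so these are package choices made
once from the qualitative description of the regimes):

| preset | mixture | benchmark (mean, q95) | status |
|---|---|---|---|
| `good_near_boundary` | 0.75·LogN(−3.8, 0.35) + 0.25·LogN(−2.9, 0.35) | ≈ 0.0325, 0.0735 | Good, near the Good/Moderate boundary |
| `moderate_far` | 0.6·LogN(−3.4, 0.5) + 0.4·LogN(−2.2, 0.5) | ≈ 0.073, 0.25 | Moderate, wide margins |
| `unimodal_lognormal` | LogN(−3.5, 0.8) | ≈ 0.042, 0.113 | Moderate; used for coverage tests |

Presets are validated at registration: the analytic mixture mean and the
numeric 95th percentile must realise the intended status class. The
`good_near_boundary` q95 (≈ 0.0735) sits ~3 Monte-Carlo standard errors
below the 0.075 boundary in a 26,280-value record; its mean (the
dominant margin) is ~20 standard errors inside Good, so the combined
benchmark status is Good for any realistic seed.

One consequence of the light-tailed storm mode (σ = 0.35): the
well-known pattern that the q95 sampling distribution is more
right-skewed than the mean's is only marginal for this preset, while it
holds uniformly for the heavier-tailed `moderate_far` and
`unimodal_lognormal`. The property tests assert the full pattern on the
heavy-tailed presets and only the OM→SM skewness relaxation on the
near-boundary one.

## Quantile conventions

All empirical 95th percentiles go through one configured rule. The
default is linear interpolation of order statistics (Hyndman–Fan type 7,
the common statistical-environment default), under which the 0.95
quantile of {1,…,100} is 95.05; a nearest-rank (`"discrete"`) rule is
available because the regulatory convention is not standardised. The
Bayesian bootstrap uses its own weighted-quantile rule (below).

## Distribution fitting

Unimodal lognormal is fitted in closed form (μ̂ = mean of logs, σ̂ =
root-mean-square deviation of logs, i.e. the ML estimate with divisor
n). Gamma and Weibull use numerical likelihood maximisation with the
location fixed at zero (scipy's `fit`). Two-component mixtures are
fitted by EM with exact weighted component ML updates: closed form for
lognormal; for gamma, `log k − ψ(k) = log(weighted mean) − weighted mean
log` solved by bracketed root-finding from the standard starting
approximation; for Weibull, the weighted shape equation solved the same
way with log-sum-exp stabilisation.

EM starts: (a) a deterministic split of the data at the median, each
half fitted unimodally; (b) a *tied* start — both components equal to
the unimodal ML fit with weights ½/½. EM is exactly stationary at the
tied start, so the best-of-restarts mixture log-likelihood can never
fall below the unimodal one; the nested-model inequality holds by
construction rather than up to local optima; (c) seeded random split
quantiles in [0.25, 0.75] (default 5). Convergence is declared when the
relative log-likelihood change falls below 1e-8 (at most 1000
iterations); a component is considered collapsed when its weight drops
below 1e-6 or its spread underflows, and a restart that collapses is
discarded. Models are ranked by raw log-likelihood, ties broken by fewer
parameters; no information criteria are applied because the comparison
of interest is the likelihood itself.

k > 2 mixtures and power-law fits are out of scope.

## Sub-sampling experiment

Each monitoring scheme draws `samples_per_year × years` values uniformly
with replacement from the full record (OM 5×3 → n = 15, SM 12×3 →
n = 36), replicated 10,000 times by default. 10,000 replicates suffice:
extending a run tenfold changes the sampling distribution of the mean by
a Kolmogorov–Smirnov distance of ≈ 0.008 (the acceptance script
estimates this expectation by averaging 20 independent nested
comparisons; a single such comparison has Monte-Carlo sd ≈ 0.0025
regardless of the underlying distribution). Sampling-distribution
summaries report bias, moment skewness m₃/m₂^1.5 (no small-sample
correction), and the HDI₉₅ width. Relative errors may be pooled across
sites by concatenation without reweighting.

## Lognormal posterior

Observations are modelled lognormal with independent uniform priors on
μ ∈ [−20, 5] (log mg P L⁻¹) and σ ∈ [1e-4, 10] — vague on any realistic
concentration. The flat prior is placed on σ itself (not σ² or log σ),
the most literal reading of "uniform priors on the parameters";
alternative parameterisations would shift posterior spread slightly and
are a known sensitivity. The posterior density is

    p(μ, σ | y) ∝ σ⁻ⁿ exp(−[S + n(μ − μ̂)²]/(2σ²)),   S = Σ(log yᵢ − μ̂)²

on the prior box. Two samplers target it:

- **exact** (default): the σ marginal (μ integrated over its box, a
  truncated-normal mass term) is tabulated on an adaptive grid — a
  1500-point log-spaced scan locates the region within 40 log-density
  units of the mode, refined to 4000 linear points — and sampled by
  inverse CDF; μ | σ is drawn from the conditional normal
  N(μ̂, σ²/n) truncated to the box. Draws are independent; no burn-in.
- **mcmc**: joint random-walk Metropolis with proposal scales
  1.7·σ̂/√n and 1.7·σ̂/√(2n) (the 2.38/√d rule), keeping `n_draws`
  after an equal burn-in. It exists to mirror the conventional MCMC
  protocol and to exercise the Gelman–Rubin diagnostic (classical PSRF;
  identical chains give √((n−1)/n) → 1).

If more than 1% of posterior mass is cut off by the prior box (computed
from the untruncated conditional for μ and an extended-grid integral for
σ in exact mode; a draw-proximity proxy in MCMC mode), a
`BoundSaturationWarning` is raised. A zero-spread sample raises an
error. Parameter draws transform to m = exp(μ + σ²/2) and
Q₉₅ = exp(μ + z₀.₉₅σ), z₀.₉₅ = Φ⁻¹(0.95) ≈ 1.6449, so the two statistic
draws are paired through the same parameter draw.

Two-component mixture posteriors are intentionally not offered for
sub-sample inference: with 15–36 observations a 5-parameter mixture is
over-parameterised and does not converge reliably.

## Bayesian bootstrap

Each posterior draw places a flat-Dirichlet weight vector on the n
observed values; the mean is the weighted average (closed-form check:
Var = Σ(yᵢ − ȳ)²/(n(n+1))) and the 95th percentile is the smallest
observed value whose cumulative weight reaches 0.95 (left-continuous,
no interpolation — the posterior support for Q₉₅ is exactly the observed
values, matching the discrete, multimodal posteriors this resampling
scheme produces; an interpolated variant is available). Because at most
one or two order statistics of a 15–36-point sample carry the 0.95
threshold, these posteriors are narrow and systematically below the
population Q₉₅ — the mechanism behind the bootstrap's poor hit rates for
the 95%ile and its optimistic status grades.

## Second-order metrics

The HDI is the shortest contiguous window of ⌈mass·N⌉ sorted draws (ties
broken by the lowest start) — verified in tests against exhaustive
window search. Interval inclusion is closed on both ends: a benchmark
exactly at an endpoint counts as a hit, which is measure-zero for
continuous posteriors but consequential for the discrete bootstrap. An
equal-tailed central interval is provided for sensitivity checks (the
summary notation HD₂.₅/HD₉₇.₅ is percentile-like, but the shortest
interval matches the stated HDI usage and is the default). Across
sub-samples, summaries report the hit rate plus 2.5%/median/97.5%
quantiles of HDI widths and RMBE values; at least 40 sub-samples are
required for the outer quantiles to mean anything.

## Status classification

Boundary values belong to the better class (the regulatory "≤"
notation). The combination rule is exactly: High if either statistic is
High, Moderate iff both are Moderate, else Good. Only the
High/Good/Moderate scheme is modelled; Poor/Bad are out of scope.

The t-test approaches assign, per statistic, the best class not
significantly excluded (right tail) or the worst class not significantly
admitted (left tail) at α = 0.01. The mean uses the one-sample t
statistic. No canonical t test exists for a 95th percentile; the default
tests the lognormal plug-in quantile on the log scale,

    T = (m_log + z₀.₉₅ s_log − log b) / (s_log √(1/n + z₀.₉₅²/(2(n−1)))),

against the t quantile with n−1 df (delta-method standard error of
m_log + z·s_log). A nonparametric binomial exceedance test (is the count
of observations above b significantly more than 5% of n) is selectable
as `q95_test="binomial"`. This construction makes benefit-of-doubt
dominance (right-tail status ≥ face-value status, left-tail ≤) hold by
construction for the mean and empirically — 1000 randomised samples in
the tests — for the percentile statistic.

Bayesian class probabilities are Monte-Carlo cell frequencies of the
paired draws; the three counts partition the draws exactly, so the
probabilities sum to 1 up to one rounding ulp.

## Experiment orchestration and seeding

`run_experiment` derives every working seed from the master seed with a
counter-based scheme keyed by (population, scheme, stage, replicate)
labels through `SeedSequence`, so reports are byte-identical under a
fixed config and increasing the replicate count never reshuffles earlier
replicates. Default protocol constants: 10,000 replicates, 1000
posterior draws, α = 0.01, OM and SM.

## Problem sizes used in the automated checks

The test suite runs the full protocol at reduced scale chosen to keep
Monte-Carlo noise well inside each assertion's tolerance: coverage of
the mean-HDI₉₅ uses 2,000 SM replicates × 1,000 draws (binomial sd of
the hit rate ≈ 0.5 percentage points against a [90, 98]% band);
method-ordering checks use 300 OM replicates on each of 5 master seeds;
EM nesting uses 20 datasets of 600 values plus one 12,000-value dataset
for the six-model ranking; the convergence and unbiasedness checks use
the full 10,000/100,000 replicate counts, which are cheap.

## Known limitations

- i.i.d. populations only; no autocorrelation, seasonality or
  flow–concentration structure (see above).
- The exact sampler's σ grid resolves the marginal to ~4000 points;
  posterior quantiles inherit a grid error far below Monte-Carlo noise
  at the default 1000 draws, but extremely peaked posteriors (n ≫ 10⁴)
  would warrant a finer grid.
- The single-interval HDI is retained even for multimodal bootstrap
  posteriors; a split HDI would be narrower there.
- Only the Irish TRP boundary table ships as a constant; other
  determinands require user-supplied boundaries.
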