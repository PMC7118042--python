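"""Posterior inference of the mean and 95th percentile from one sub-sample.

Two routes are offered, mirroring the two candidate models that remain
identifiable on 15-36 observations:

**Lognormal model.**  Observations are lognormal with parameters
(mu, sigma) on the log scale, under independent uniform (flat) priors on a
bounded box.  The posterior density is

    p(mu, sigma | y)  ∝  sigma^(-n) exp( -sum (log y_i - mu)^2 / (2 sigma^2) )

restricted to the prior box.  ``mode="exact"`` draws independent samples
by inverse-CDF from the sigma marginal on an adaptive grid followed by the
conditional (truncated) normal for mu; no burn-in is needed.
``mode="mcmc"`` runs a random-walk Metropolis sampler keeping ``n_draws``
realisations after an equal burn-in, mirroring the conventional MCMC
protocol and giving the Gelman-Rubin diagnostic something to check.
Parameter draws are transformed to the statistics of interest:
mean = exp(mu + sigma^2/2) and q95 = exp(mu + z_0.95 sigma).

**Bayesian bootstrap** (Rubin).  Each posterior draw places flat-Dirichlet
weights on the n observed values; the mean is the weighted average and the
95th percentile a weighted quantile of the discrete weighted distribution.
Its posterior support is discrete — q95 draws are always observed values
under the default left-continuous quantile rule.

Both return paired draws, so joint events over (mean, q95) — as needed
for status-class probabilities — are evaluated draw by draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .quantiles import weighted_quantile

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "BoundSaturationWarning",
    "lognormal_posterior",
    "bayesian_bootstrap",
    "gelman_rubin",
]

_Z95 = float(stats.norm.ppf(0.95))


class BoundSaturationWarning(UserWarning):
    """Posterior mass piles up at a prior bound; the prior box is too tight."""


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior box for the lognormal parameters.

    Defaults are vague on any realistic concentration scale:
    mu in [-20, 5] (log mg P L^-1) and sigma in [1e-4, 10].
    """

    mu_bounds: tuple[float, float] = (-20.0, 5.0)
    sigma_bounds: tuple[float, float] = (1e-4, 10.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.mu_bounds, self.sigma_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("prior bounds must be finite with lower < upper")
        if self.sigma_bounds[0] < 0:
            raise ValueError("sigma lower bound must be >= 0")


@dataclass(frozen=True)
class PosteriorDraws:
    """Paired posterior draws of (mean, q95), plus parameter draws if parametric."""

    method: str
    draws_mean: np.ndarray = field(repr=False)
    draws_q95: np.ndarray = field(repr=False)
    paired: bool = True
    mu: Optional[np.ndarray] = field(default=None, repr=False)
    sigma: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.draws_mean, dtype=float)
        q = np.asarray(self.draws_q95, dtype=float)
        object.__setattr__(self, "draws_mean", m)
        object.__setattr__(self, "draws_q95", q)
        if m.shape != q.shape or m.ndim != 1:
            raise ValueError("draws_mean and draws_q95 must be equal-length vectors")
        if not self.paired:
            raise ValueError("posterior draws must be paired")
        if m.size and (np.any(m <= 0) or np.any(q <= 0)):
            raise ValueError("concentration draws must be positive")

    def __len__(self) -> int:
        return self.draws_mean.size

    def to_frame(self) -> pd.DataFrame:
        data = {"draw": np.arange(len(self)), "mean": self.draws_mean, "q95": self.draws_q95}
        if self.mu is not None:
            data["mu"] = self.mu
            data["sigma"] = self.sigma
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _log_sufficient(sample: np.ndarray) -> tuple[int, float, float]:
    """(n, mean of log y, sum of squared log deviations)."""
    logs = np.log(sample)
    n = logs.size
    mhat = float(logs.mean())
    ss = float(np.sum((logs - mhat) ** 2))
    return n, mhat, ss


def _sigma_log_marginal(sig: np.ndarray, n: int, mhat: float, ss: float, prior: PriorSpec) -> np.ndarray:
    """Unnormalised log density of sigma with mu integrated over its box."""
    mu_lo, mu_hi = prior.mu_bounds
    root_n = np.sqrt(n)
    z_hi = (mu_hi - mhat) * root_n / sig
    z_lo = (mu_lo - mhat) * root_n / sig
    mass = special.ndtr(z_hi) - special.ndtr(z_lo)
    return -(n - 1) * np.log(sig) - ss / (2.0 * sig**2) + np.log(np.maximum(mass, 1e-300))


def _warn_saturation(frac: float, label: str) -> None:
    if frac > 0.01:
        warnings.warn(
            f"{frac:.1%} of posterior mass for {label} is cut off by the prior bounds; "
            "widen the prior box",
            BoundSaturationWarning,
            stacklevel=4,
        )


def _check_saturation_draws(draws: np.ndarray, bounds: tuple[float, float], label: str) -> None:
    # draw-based proxy used in MCMC mode: mass piling onto the outer 0.5% of the box
    lo, hi = bounds
    eps = 5e-3 * (hi - lo)
    _warn_saturation(float(np.mean((draws <= lo + eps) | (draws >= hi - eps))) , label)


def _draws_from_params(mu: np.ndarray, sigma: np.ndarray, method: str) -> PosteriorDraws:
    return PosteriorDraws(
        method=method,
        draws_mean=np.exp(mu + sigma**2 / 2.0),
        draws_q95=np.exp(mu + _Z95 * sigma),
        mu=mu,
        sigma=sigma,
    )


def _exact_lognormal(sample: np.ndarray, n_draws: int, prior: PriorSpec, rng: np.random.Generator) -> PosteriorDraws:
    n, mhat, ss = _log_sufficient(sample)
    sig_lo, sig_hi = prior.sigma_bounds
    sig_lo = max(sig_lo, 1e-12)

    # locate the high-density region of the sigma marginal on a coarse
    # log-spaced grid, then refine linearly before inverse-CDF sampling
    coarse = np.geomspace(sig_lo, sig_hi, 1500)
    logp = _sigma_log_marginal(coarse, n, mhat, ss, prior)
    keep = logp > logp.max() - 40.0
    i0 = max(int(np.argmax(keep)) - 1, 0)
    i1 = min(len(coarse) - int(np.argmax(keep[::-1])), len(coarse) - 1)
    fine = np.linspace(coarse[i0], coarse[i1], 4000)
    logp_f = _sigma_log_marginal(fine, n, mhat, ss, prior)
    dens = np.exp(logp_f - logp_f.max())
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(fine))])
    if cdf[-1] <= 0:
        raise ValueError("sigma marginal has no mass inside the prior box")
    cdf /= cdf[-1]
    # strictly increasing grid for interpolation
    u = rng.random(n_draws)
    sigma = np.interp(u, cdf, fine)

    # mu | sigma ~ Normal(mhat, sigma/sqrt(n)) truncated to the mu box
    mu_lo, mu_hi = prior.mu_bounds
    sd = sigma / np.sqrt(n)
    p_lo = special.ndtr((mu_lo - mhat) / sd)
    p_hi = special.ndtr((mu_hi - mhat) / sd)
    v = rng.random(n_draws)
    mu = mhat + sd * special.ndtri(p_lo + v * (p_hi - p_lo))

    # saturation: untruncated conditional mass of mu falling outside its box,
    # and sigma-marginal mass outside [sig_lo, sig_hi] on an extended grid
    _warn_saturation(float(np.mean(p_lo + (1.0 - p_hi))), "mu")
    ext = np.geomspace(max(sig_lo * 1e-3, 1e-15), sig_hi * 1e3, 3000)
    logp_ext = _sigma_log_marginal(ext, n, mhat, ss, prior)
    dens_ext = np.exp(logp_ext - logp_ext.max())
    total = np.trapezoid(dens_ext, ext)
    inside = (ext >= sig_lo) & (ext <= sig_hi)
    in_mass = np.trapezoid(dens_ext[inside], ext[inside]) if inside.sum() > 1 else 0.0
    if total > 0:
        _warn_saturation(float(1.0 - in_mass / total), "sigma")
    return _draws_from_params(mu, sigma, "lognormal")


def _mcmc_lognormal(sample: np.ndarray, n_draws: int, prior: PriorSpec, rng: np.random.Generator) -> PosteriorDraws:
    n, mhat, ss = _log_sufficient(sample)
    shat = np.sqrt(ss / n)
    mu_lo, mu_hi = prior.mu_bounds
    sig_lo, sig_hi = prior.sigma_bounds

    def logpost(mu: float, sig: float) -> float:
        if not (mu_lo <= mu <= mu_hi and sig_lo <= sig <= sig_hi):
            return -np.inf
        return -n * np.log(sig) - (ss + n * (mu - mhat) ** 2) / (2.0 * sig**2)

    # joint random-walk scale 2.38/sqrt(d) times the posterior scales
    step_mu = 1.7 * shat / np.sqrt(n)
    step_sig = 1.7 * shat / np.sqrt(2.0 * n)
    mu = float(np.clip(mhat, mu_lo, mu_hi))
    sig = float(np.clip(shat, max(sig_lo, 1e-6), sig_hi))
    lp = logpost(mu, sig)

    burn_in = n_draws
    total = burn_in + n_draws
    steps = rng.normal(size=(total, 2))
    unif = np.log(rng.random(total))
    mus = np.empty(n_draws)
    sigs = np.empty(n_draws)
    for t in range(total):
        mu_p = mu + step_mu * steps[t, 0]
        sig_p = sig + step_sig * steps[t, 1]
        lp_p = logpost(mu_p, sig_p)
        if lp_p - lp > unif[t]:
            mu, sig, lp = mu_p, sig_p, lp_p
        if t >= burn_in:
            mus[t - burn_in] = mu
            sigs[t - burn_in] = sig

    _check_saturation_draws(sigs, prior.sigma_bounds, "sigma")
    _check_saturation_draws(mus, prior.mu_bounds, "mu")
    return _draws_from_params(mus, sigs, "lognormal")


def lognormal_posterior(
    sample,
    n_draws: int = 1000,
    prior: Optional[PriorSpec] = None,
    seed: int = 0,
    mode: str = "exact",
) -> PosteriorDraws:
    """Posterior of (mean, q95) under the lognormal model with flat priors.

    ``mode="exact"`` (default) draws independent posterior samples;
    ``mode="mcmc"`` keeps ``n_draws`` random-walk realisations after an
    equal burn-in.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 1 or sample.size < 2:
        raise ValueError("need a vector of at least 2 observations")
    if np.any(sample <= 0):
        raise ValueError("lognormal model requires strictly positive observations")
    if np.ptp(sample) == 0:
        raise ValueError("degenerate sample: zero spread on the log scale")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    prior = prior or PriorSpec()
    rng = np.random.default_rng(seed)
    if mode == "exact":
        return _exact_lognormal(sample, n_draws, prior, rng)
    if mode == "mcmc":
        return _mcmc_lognormal(sample, n_draws, prior, rng)
    raise ValueError(f"mode must be 'exact' or 'mcmc', got {mode!r}")


def bayesian_bootstrap(
    sample,
    n_draws: int = 1000,
    seed: int = 0,
    q95_rule: str = "left",
) -> PosteriorDraws:
    """Rubin's Bayesian bootstrap posterior of (mean, q95).

    Each draw samples a flat-Dirichlet weight vector over the n observed
    values; the mean is the weighted average, the 95th percentile the
    weighted quantile of the discrete weighted distribution (default rule:
    smallest order statistic whose cumulative weight reaches 0.95).
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 1 or sample.size < 2:
        raise ValueError("need a vector of at least 2 observations")
    if np.any(sample <= 0):
        raise ValueError("concentrations must be strictly positive")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    n = sample.size
    weights = rng.dirichlet(np.ones(n), size=n_draws)
    draws_mean = weights @ sample

    order = np.argsort(sample, kind="stable")
    sorted_values = sample[order]
    cum = np.cumsum(weights[:, order], axis=1)
    if q95_rule == "left":
        idx = np.argmax(cum >= 0.95, axis=1)
        draws_q95 = sorted_values[idx]
    elif q95_rule == "interpolated":
        draws_q95 = np.array(
            [weighted_quantile(sample, w, 0.95, rule="interpolated") for w in weights]
        )
    else:
        raise ValueError(f"q95_rule must be 'left' or 'interpolated', got {q95_rule!r}")
    return PosteriorDraws(
        method="bayesian_bootstrap", draws_mean=draws_mean, draws_q95=draws_q95
    )


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor sqrt(((n-1)/n W + B/n) / W).

    W is the mean within-chain variance and B = n var(chain means).
    Identical chains give sqrt((n-1)/n), i.e. 1 in the large-n limit;
    values well above 1.1 indicate nonconvergence.
    """
    arrays = [np.asarray(c, dtype=float) for c in chains]
    if len(arrays) < 2:
        raise ValueError("need at least 2 chains")
    n = arrays[0].size
    if n < 10 or any(a.size != n for a in arrays):
        raise ValueError("chains must have equal lengths >= 10")
    x = np.stack(arrays)
    within = float(np.mean(np.var(x, axis=1, ddof=1)))
    between = float(n * np.var(x.mean(axis=1), ddof=1))
    if within == 0:
        raise ValueError("zero within-chain variance")
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))
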