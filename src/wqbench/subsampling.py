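"""Monte-Carlo sub-sampling of a high-frequency population record.

Regulatory monitoring observes a river only a handful of times per year:
operational monitoring (OM) takes 5 samples/year and surveillance
monitoring (SM) 12/year, pooled over 3 years per classification.  The
sampling distribution of a statistic (mean or 95th percentile) under such
a scheme is approximated by drawing many random sub-samples, with
replacement and unconstrained in time, from the full hourly record and
recomputing the statistic each time.  The statistic computed on the full
record is the benchmark; deviations are expressed as relative error in
percent, and per-site error distributions may be pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import hdi
from .quantiles import quantile
from .synthetic_data import PopulationSeries

__all__ = [
    "MonitoringScheme",
    "Subsample",
    "SamplingDistribution",
    "SamplingSummary",
    "OM",
    "SM",
    "draw_subsamples",
    "subsample_statistics",
    "statistic",
    "relative_error",
    "pool_errors",
    "summarize_sampling",
    "ks_between",
]


@dataclass(frozen=True)
class MonitoringScheme:
    """A regulatory sampling design: samples_per_year x years observations."""

    name: str
    samples_per_year: int
    years: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("scheme must yield at least 2 observations")

    @property
    def n(self) -> int:
        return self.samples_per_year * self.years


#: Operational monitoring: 5 samples/year over 3 years (n = 15).
OM = MonitoringScheme("OM", 5, 3)
#: Surveillance monitoring: 12 samples/year (monthly) over 3 years (n = 36).
SM = MonitoringScheme("SM", 12, 3)


@dataclass(frozen=True)
class Subsample:
    """One low-frequency draw from the population."""

    values: np.ndarray = field(repr=False)
    indices: np.ndarray = field(repr=False)
    scheme: MonitoringScheme
    replicate: int


@dataclass(frozen=True)
class SamplingDistribution:
    """Monte-Carlo distribution of one statistic across sub-sample replicates."""

    statistic: str
    draws: np.ndarray = field(repr=False)
    benchmark: float

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        object.__setattr__(self, "draws", draws)
        if self.statistic not in ("mean", "q95"):
            raise ValueError(f"statistic must be 'mean' or 'q95', got {self.statistic!r}")
        if not self.benchmark > 0:
            raise ValueError("benchmark statistic must be positive")

    def relative_errors(self) -> np.ndarray:
        return relative_error(self.draws, self.benchmark)

    def to_csv(self, path) -> None:
        pd.DataFrame({self.statistic: self.draws}).to_csv(path, index=False)


def _draw_indices(n_population: int, scheme: MonitoringScheme, reps: int, seed: int) -> np.ndarray:
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n_population < 1:
        raise ValueError("population must be nonempty")
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_population, size=(reps, scheme.n))


def draw_subsamples(
    series: PopulationSeries,
    scheme: MonitoringScheme,
    reps: int,
    seed: int,
) -> list[Subsample]:
    """``reps`` uniform-with-replacement sub-samples of size scheme.n."""
    idx = _draw_indices(len(series), scheme, reps, seed)
    values = series.values[idx]
    return [
        Subsample(values=values[r], indices=idx[r], scheme=scheme, replicate=r)
        for r in range(reps)
    ]


def subsample_statistics(
    series: PopulationSeries,
    scheme: MonitoringScheme,
    reps: int,
    seed: int,
    which: str,
    quantile_rule: str = "linear",
) -> SamplingDistribution:
    """Vectorised sampling distribution of one statistic.

    Equivalent to mapping :func:`statistic` over :func:`draw_subsamples`
    (same seed gives the same index draws) but avoids materialising the
    sub-sample objects, which matters at 10^5 replicates.
    """
    idx = _draw_indices(len(series), scheme, reps, seed)
    values = series.values[idx]
    if which == "mean":
        draws = values.mean(axis=1)
    elif which == "q95":
        method = {"linear": "linear", "discrete": "inverted_cdf"}[quantile_rule]
        draws = np.quantile(values, 0.95, axis=1, method=method)
    else:
        raise ValueError(f"statistic must be 'mean' or 'q95', got {which!r}")
    benchmark = statistic(series.values, which, quantile_rule)
    return SamplingDistribution(statistic=which, draws=draws, benchmark=benchmark)


def statistic(values, which: str, quantile_rule: str = "linear") -> float:
    """Arithmetic mean or 95th percentile under the configured quantile rule."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value vector")
    if which == "mean":
        return float(values.mean())
    if which == "q95":
        return quantile(values, 0.95, quantile_rule)
    raise ValueError(f"statistic must be 'mean' or 'q95', got {which!r}")


def relative_error(x_i, x_b: float):
    """Relative error (X_i - X_b) / X_b x 100, in percent."""
    if not x_b > 0:
        raise ValueError("benchmark statistic must be positive")
    return (np.asarray(x_i, dtype=float) - x_b) / x_b * 100.0


def pool_errors(per_site_errors: Sequence[np.ndarray]) -> np.ndarray:
    """Concatenate per-site relative-error vectors; no reweighting."""
    if len(per_site_errors) == 0:
        raise ValueError("need at least one site")
    return np.concatenate([np.asarray(e, dtype=float) for e in per_site_errors])


class SamplingSummary(NamedTuple):
    bias: float
    skewness: float
    hdi95_width: float


def summarize_sampling(dist: SamplingDistribution) -> SamplingSummary:
    """Bias, moment skewness (m3/m2^1.5) and HDI95 width of a sampling distribution."""
    draws = dist.draws
    if draws.size < 10:
        raise ValueError("need at least 10 replicates to summarise")
    bias = float(draws.mean() - dist.benchmark)
    if np.ptp(draws) == 0:
        warnings.warn("zero-variance sampling distribution: skewness undefined", RuntimeWarning)
        skewness = float("nan")
    else:
        skewness = float(stats.skew(draws, bias=True))
    interval = hdi(draws, 0.95)
    return SamplingSummary(bias=bias, skewness=skewness, hdi95_width=interval.width)


def ks_between(dist_a: SamplingDistribution, dist_b: SamplingDistribution) -> float:
    """Two-sample Kolmogorov-Smirnov statistic between two sampling distributions."""
    if dist_a.statistic != dist_b.statistic:
        raise ValueError(
            f"cannot compare {dist_a.statistic!r} with {dist_b.statistic!r} draws"
        )
    if dist_a.draws.size == 0 or dist_b.draws.size == 0:
        raise ValueError("empty sampling distribution")
    return float(stats.ks_2samp(dist_a.draws, dist_b.draws).statistic)
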