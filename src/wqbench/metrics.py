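"""Second-order uncertainty metrics for posterior distributions.

A posterior computed from a low-frequency sub-sample is judged against the
benchmark statistic of the full high-frequency record through

* the 95% highest density interval (HDI95) — the shortest interval
  containing 95% of the posterior draws (Kruschke's sorted-window
  algorithm),
* the hit rate — the percentage of sub-samples whose interval contains
  the benchmark,
* the relative mean bias error (RMBE) — the mean relative deviation of
  the posterior draws from the benchmark, in percent.

Across many sub-samples the HDI widths and RMBE values are summarised by
their 2.5%/median/97.5% quantiles alongside the hit rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CredibleInterval",
    "SecondOrderSummary",
    "hdi",
    "central_interval",
    "hit_rate",
    "rmbe",
    "summarize_second_order",
]


@dataclass(frozen=True)
class CredibleInterval:
    lower: float
    upper: float
    mass: float = 0.95
    kind: str = "hdi"

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("interval lower bound exceeds upper bound")
        if not 0.0 < self.mass < 1.0:
            raise ValueError("interval mass must be in (0, 1)")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        """Closed on both ends: an endpoint hit counts."""
        return self.lower <= x <= self.upper


def hdi(draws, mass: float = 0.95) -> CredibleInterval:
    """Shortest contiguous interval of sorted draws holding ceil(mass*N) draws.

    Ties between equally short windows are broken by the lowest start.
    """
    draws = np.sort(np.asarray(draws, dtype=float))
    n = draws.size
    if n < 10:
        raise ValueError("need at least 10 draws for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    n_inc = int(np.ceil(mass * n))
    n_inc = min(n_inc, n)
    widths = draws[n_inc - 1 :] - draws[: n - n_inc + 1]
    start = int(np.argmin(widths))  # argmin returns the first minimum
    return CredibleInterval(
        lower=float(draws[start]), upper=float(draws[start + n_inc - 1]), mass=mass, kind="hdi"
    )


def central_interval(draws, mass: float = 0.95) -> CredibleInterval:
    """Equal-tailed interval, for sensitivity checks against the HDI."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 10:
        raise ValueError("need at least 10 draws")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    alpha = (1.0 - mass) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return CredibleInterval(lower=float(lo), upper=float(hi), mass=mass, kind="central")


def hit_rate(intervals: Sequence[CredibleInterval], x_b: float) -> float:
    """Percentage of intervals containing the benchmark statistic."""
    intervals = list(intervals)
    if not intervals:
        raise ValueError("need at least one interval")
    hits = sum(iv.contains(x_b) for iv in intervals)
    return 100.0 * hits / len(intervals)


def rmbe(draws, x_b: float) -> float:
    """Relative mean bias error in percent; positive means overestimation."""
    if not x_b > 0:
        raise ValueError("benchmark statistic must be positive")
    draws = np.asarray(draws, dtype=float)
    if draws.size < 1:
        raise ValueError("need at least one draw")
    return float(np.mean((draws - x_b) / x_b) * 100.0)


@dataclass(frozen=True)
class SecondOrderSummary:
    """Hit rate plus 2.5%/median/97.5% quantiles of HDI width and RMBE."""

    hit_rate: float
    hdi_width_q: tuple[float, float, float]
    rmbe_q: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.hit_rate <= 100.0:
            raise ValueError("hit rate must be a percentage")
        for triple in (self.hdi_width_q, self.rmbe_q):
            if not (triple[0] <= triple[1] <= triple[2]):
                raise ValueError("quantile triple must be nondecreasing")

    def to_dict(self) -> dict:
        return {
            "hit_rate_percent": self.hit_rate,
            "hdi95_width_mgP_L": dict(zip(("q2.5", "median", "q97.5"), self.hdi_width_q)),
            "rmbe_percent": dict(zip(("q2.5", "median", "q97.5"), self.rmbe_q)),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def summarize_second_order(
    per_subsample: Sequence[tuple[CredibleInterval, float]],
    x_b: float,
) -> SecondOrderSummary:
    """Summarise (HDI, RMBE) pairs across sub-samples against one benchmark."""
    per_subsample = list(per_subsample)
    if len(per_subsample) < 40:
        raise ValueError("need at least 40 sub-samples for stable 2.5/97.5% quantiles")
    intervals = [iv for iv, _ in per_subsample]
    widths = np.array([iv.width for iv in intervals])
    rmbes = np.array([r for _, r in per_subsample], dtype=float)
    probs = [0.025, 0.5, 0.975]
    return SecondOrderSummary(
        hit_rate=hit_rate(intervals, x_b),
        hdi_width_q=tuple(float(v) for v in np.quantile(widths, probs)),
        rmbe_q=tuple(float(v) for v in np.quantile(rmbes, probs)),
    )
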