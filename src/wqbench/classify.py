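"""Physicochemical status classification against regulatory class boundaries.

Irish rivers are graded High / Good / Moderate for a nutrient by comparing
two statistics — the mean and the 95th percentile of concentration — with
predefined boundaries.  The two statistics are assessed separately and then
combined: the river is High if *either* statistic is High, Moderate only if
*both* are Moderate, and Good otherwise.  This module implements that
calculus for

* the face-value approach (raw sample statistics, no uncertainty),
* one-sided t tests at 99% confidence (right tail = benefit-of-doubt,
  left tail = fail-safe),
* Bayesian posterior class probabilities evaluated over paired posterior
  draws of (mean, q95),

plus the misgrading (over-/under-grading) frequency of a set of assigned
statuses against a benchmark status.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .quantiles import quantile

__all__ = [
    "StatusClass",
    "ClassBoundaries",
    "ClassProbabilities",
    "IRISH_TRP_BOUNDARIES",
    "DegenerateSampleError",
    "classify_statistic",
    "combine_status",
    "face_value_status",
    "t_test_status",
    "bayes_class_probabilities",
    "misgrade_frequency",
    "MisgradeFrequency",
]

_Z95 = float(stats.norm.ppf(0.95))


class DegenerateSampleError(ValueError):
    """Sample has zero spread; the requested test statistic is undefined."""


class StatusClass(enum.IntEnum):
    """Physicochemical status grade; the integer order encodes quality (High best)."""

    Moderate = 0
    Good = 1
    High = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class ClassBoundaries:
    """Upper concentration bounds (mg P L^-1) of High and Good per statistic.

    Boundary values belong to the better class (the regulatory tables use
    "<=" for the upper bound of each class).
    """

    mean_high_upper: float
    mean_good_upper: float
    q95_high_upper: float
    q95_good_upper: float

    def __post_init__(self) -> None:
        for which in ("mean", "q95"):
            hi, good = self.bounds(which)
            if not 0 < hi < good:
                raise ValueError(
                    f"require 0 < high_upper < good_upper for {which}, got ({hi}, {good})"
                )

    def bounds(self, which: str) -> tuple[float, float]:
        if which == "mean":
            return self.mean_high_upper, self.mean_good_upper
        if which == "q95":
            return self.q95_high_upper, self.q95_good_upper
        raise ValueError(f"unknown statistic {which!r}; expected 'mean' or 'q95'")

    @classmethod
    def from_dict(cls, d: dict) -> "ClassBoundaries":
        return cls(
            mean_high_upper=float(d["mean"]["high_upper"]),
            mean_good_upper=float(d["mean"]["good_upper"]),
            q95_high_upper=float(d["q95"]["high_upper"]),
            q95_good_upper=float(d["q95"]["good_upper"]),
        )

    def to_dict(self) -> dict:
        return {
            "mean": {"high_upper": self.mean_high_upper, "good_upper": self.mean_good_upper},
            "q95": {"high_upper": self.q95_high_upper, "good_upper": self.q95_good_upper},
        }


#: Irish Water Framework Directive boundaries for total reactive phosphorus.
IRISH_TRP_BOUNDARIES = ClassBoundaries(0.025, 0.035, 0.045, 0.075)


@dataclass(frozen=True)
class ClassProbabilities:
    """Posterior probability of each status class; sums to one exactly."""

    p_high: float
    p_good: float
    p_moderate: float

    def __post_init__(self) -> None:
        for p in (self.p_high, self.p_good, self.p_moderate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(self.p_high + self.p_good + self.p_moderate - 1.0) > 1e-12:
            raise ValueError("class probabilities must sum to 1")

    def argmax_status(self) -> StatusClass:
        triples = [
            (self.p_high, StatusClass.High),
            (self.p_good, StatusClass.Good),
            (self.p_moderate, StatusClass.Moderate),
        ]
        return max(triples, key=lambda t: t[0])[1]

    def to_dict(self) -> dict:
        return {"High": self.p_high, "Good": self.p_good, "Moderate": self.p_moderate}


def classify_statistic(value: float, which: str, boundaries: ClassBoundaries = IRISH_TRP_BOUNDARIES) -> StatusClass:
    """Grade a single statistic; values on a boundary go to the better class."""
    if not value > 0:
        raise ValueError(f"concentration statistic must be positive, got {value}")
    high_upper, good_upper = boundaries.bounds(which)
    if value <= high_upper:
        return StatusClass.High
    if value <= good_upper:
        return StatusClass.Good
    return StatusClass.Moderate


def combine_status(mean_class: StatusClass, q95_class: StatusClass) -> StatusClass:
    """Combine per-statistic grades: High if either is High; Moderate iff both are."""
    if mean_class == StatusClass.High or q95_class == StatusClass.High:
        return StatusClass.High
    if mean_class == StatusClass.Moderate and q95_class == StatusClass.Moderate:
        return StatusClass.Moderate
    return StatusClass.Good


def face_value_status(
    sample,
    boundaries: ClassBoundaries = IRISH_TRP_BOUNDARIES,
    quantile_rule: str = "linear",
) -> StatusClass:
    """Status from the raw sample mean and 95th percentile, uncertainty ignored."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    mean_class = classify_statistic(float(sample.mean()), "mean", boundaries)
    q95_class = classify_statistic(quantile(sample, 0.95, quantile_rule), "q95", boundaries)
    return combine_status(mean_class, q95_class)


def _mean_t(sample: np.ndarray, boundary: float) -> float:
    n = sample.size
    s = sample.std(ddof=1)
    return float((sample.mean() - boundary) / (s / np.sqrt(n)))


def _q95_t_lognormal(sample: np.ndarray, boundary: float) -> float:
    # Approximate one-sided test for a lognormal 0.95 quantile on the log
    # scale: the plug-in estimate m + z*s has standard error
    # s*sqrt(1/n + z^2/(2(n-1))) by the delta method.
    logs = np.log(sample)
    n = logs.size
    m, s = logs.mean(), logs.std(ddof=1)
    se = s * np.sqrt(1.0 / n + _Z95**2 / (2.0 * (n - 1)))
    return float((m + _Z95 * s - np.log(boundary)) / se)


def _q95_binomial_significant(sample: np.ndarray, boundary: float, alpha: float, tail: str) -> bool:
    # Nonparametric alternative: the true q95 exceeds the boundary iff the
    # exceedance probability P(X > boundary) exceeds 0.05.
    n = sample.size
    k = int(np.sum(sample > boundary))
    if tail == "right":  # evidence that q95 is above the boundary
        return stats.binom.sf(k - 1, n, 0.05) < alpha
    return stats.binom.cdf(k, n, 0.05) < alpha  # evidence that it is below


def t_test_status(
    sample,
    boundaries: ClassBoundaries = IRISH_TRP_BOUNDARIES,
    alpha: float = 0.01,
    tail: str = "right",
    q95_test: str = "lognormal",
) -> StatusClass:
    """Status by one-sided significance tests against the class boundaries.

    The right tail ("benefit of doubt") assigns each statistic the best
    class not significantly excluded: a statistic is downgraded only when
    it is significantly *above* a boundary.  The left tail ("fail-safe")
    mirrors this: it starts from Moderate and upgrades only on significant
    evidence that the statistic is *below* a boundary.

    The mean uses the one-sample t statistic.  The 95th percentile has no
    canonical t test; the default ``q95_test="lognormal"`` tests the
    lognormal-theory plug-in quantile on the log scale (see
    :func:`_q95_t_lognormal`), and ``"binomial"`` uses the exceedance-count
    binomial test instead.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 3:
        raise ValueError("t-test classification requires n >= 3")
    if np.ptp(sample) == 0:
        raise DegenerateSampleError("sample has zero spread; t statistics undefined")
    if np.any(sample <= 0):
        raise ValueError("concentrations must be positive")
    if tail not in ("right", "left"):
        raise ValueError(f"tail must be 'right' or 'left', got {tail!r}")
    if q95_test not in ("lognormal", "binomial"):
        raise ValueError(f"q95_test must be 'lognormal' or 'binomial', got {q95_test!r}")

    tcrit = float(stats.t.ppf(1.0 - alpha, sample.size - 1))

    def significant(which: str, boundary: float, direction: str) -> bool:
        if which == "mean":
            t = _mean_t(sample, boundary)
        elif q95_test == "lognormal":
            t = _q95_t_lognormal(sample, boundary)
        else:
            return _q95_binomial_significant(sample, boundary, alpha, direction)
        return t > tcrit if direction == "right" else t < -tcrit

    def grade(which: str) -> StatusClass:
        high_upper, good_upper = boundaries.bounds(which)
        if tail == "right":
            if significant(which, good_upper, "right"):
                return StatusClass.Moderate
            if significant(which, high_upper, "right"):
                return StatusClass.Good
            return StatusClass.High
        if significant(which, high_upper, "left"):
            return StatusClass.High
        if significant(which, good_upper, "left"):
            return StatusClass.Good
        return StatusClass.Moderate

    return combine_status(grade("mean"), grade("q95"))


def bayes_class_probabilities(posterior, boundaries: ClassBoundaries = IRISH_TRP_BOUNDARIES) -> ClassProbabilities:
    """Monte-Carlo class probabilities from paired posterior draws.

    ``posterior`` is any object with paired, equal-length ``draws_mean``
    and ``draws_q95`` vectors (e.g. :class:`wqbench.bayes_infer.PosteriorDraws`).
    The three probabilities partition the draws exactly:
    High = (mean in High) or (q95 in High); Moderate = both in Moderate;
    Good = everything else.  The three counts partition the draws exactly,
    so the probabilities sum to 1 up to one rounding ulp.
    """
    if not getattr(posterior, "paired", True):
        raise ValueError("class probabilities require paired draws")
    m = np.asarray(posterior.draws_mean, dtype=float)
    q = np.asarray(posterior.draws_q95, dtype=float)
    if m.shape != q.shape or m.ndim != 1:
        raise ValueError("draws_mean and draws_q95 must be equal-length vectors")
    if m.size < 1:
        raise ValueError("no posterior draws")

    def grades(values: np.ndarray, which: str) -> np.ndarray:
        hi, good = boundaries.bounds(which)
        out = np.full(values.shape, StatusClass.Moderate, dtype=int)
        out[values <= good] = StatusClass.Good
        out[values <= hi] = StatusClass.High
        return out

    gm = grades(m, "mean")
    gq = grades(q, "q95")
    n = m.size
    n_high = int(np.sum((gm == StatusClass.High) | (gq == StatusClass.High)))
    n_moderate = int(np.sum((gm == StatusClass.Moderate) & (gq == StatusClass.Moderate)))
    n_good = n - n_high - n_moderate
    return ClassProbabilities(p_high=n_high / n, p_good=n_good / n, p_moderate=n_moderate / n)


class MisgradeFrequency(NamedTuple):
    percent_correct: float
    percent_over: float
    percent_under: float


def misgrade_frequency(assigned: Sequence[StatusClass], benchmark: StatusClass) -> MisgradeFrequency:
    """Percent of assigned statuses equal to / better than / worse than benchmark."""
    assigned = list(assigned)
    if not assigned:
        raise ValueError("no assigned statuses")
    n = len(assigned)
    over = sum(a > benchmark for a in assigned)
    under = sum(a < benchmark for a in assigned)
    correct = n - over - under
    return MisgradeFrequency(100.0 * correct / n, 100.0 * over / n, 100.0 * under / n)


def classification_record(method: str, mean_class: StatusClass, q95_class: StatusClass,
                          probabilities: ClassProbabilities | None = None) -> str:
    """One JSON classification report line."""
    rec = {
        "method": method,
        "mean_class": mean_class.name,
        "q95_class": q95_class.name,
        "status": combine_status(mean_class, q95_class).name,
    }
    if probabilities is not None:
        rec["probabilities"] = probabilities.to_dict()
    return json.dumps(rec)
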