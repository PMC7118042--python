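"""Quantile rules shared across the package.

Regulatory statistics depend on the convention used for the empirical
95th percentile.  All modules route through :func:`quantile` so that one
configured rule applies everywhere.  The default, ``"linear"``, is the
linear interpolation of order statistics (Hyndman-Fan type 7, the common
statistical-environment default), under which the 0.95 quantile of
``{1, ..., 100}`` is 95.05.  ``"discrete"`` is the nearest-rank rule:
the smallest order statistic whose empirical CDF reaches p.
"""

from __future__ import annotations

import numpy as np

_RULE_TO_NUMPY = {
    "linear": "linear",
    "discrete": "inverted_cdf",
}


def quantile(values, p: float, rule: str = "linear") -> float:
    """p-quantile of ``values`` under the configured empirical rule."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("quantile of an empty vector is undefined")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    try:
        method = _RULE_TO_NUMPY[rule]
    except KeyError:
        raise ValueError(f"unknown quantile rule {rule!r}; choose from {sorted(_RULE_TO_NUMPY)}") from None
    return float(np.quantile(values, p, method=method))


def weighted_quantile(values, weights, p: float, rule: str = "left") -> float:
    """p-quantile of the discrete weighted distribution {(value_i, weight_i)}.

    ``"left"`` (default) returns the smallest observed value whose
    cumulative weight reaches p, so the result is always one of the
    observed values — the discrete-support convention of the Bayesian
    bootstrap.  ``"interpolated"`` interpolates linearly between adjacent
    order statistics on the cumulative-weight scale.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape or values.size == 0:
        raise ValueError("values and weights must be equal-length nonempty vectors")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order]) / total
    if rule == "left":
        idx = int(np.searchsorted(cw, p, side="left"))
        idx = min(idx, v.size - 1)
        return float(v[idx])
    if rule == "interpolated":
        return float(np.interp(p, cw, v))
    raise ValueError(f"unknown weighted-quantile rule {rule!r}")
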