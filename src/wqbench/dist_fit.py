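"""Maximum-likelihood fitting of unimodal and two-component mixtures.

High-frequency concentration records are compared against candidate
parametric shapes — lognormal, gamma and Weibull, each as a single
distribution and as a two-component mixture — and ranked by total
log-likelihood.  Unimodal lognormal has a closed-form ML solution; gamma
and Weibull use numerical likelihood maximisation (scipy, location fixed
at zero).  Mixtures are fitted by EM with weighted component ML updates.

EM starts: (a) a deterministic split of the data at an empirical quantile
(median by default), each half fitted unimodally; (b) a "tied" start with
both components equal to the unimodal ML fit and equal weights — EM is
stationary there, so the best mixture log-likelihood can never fall below
the unimodal one; (c) seeded random split quantiles.  The best converged
restart wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .synthetic_data import MixtureSpec

__all__ = [
    "FitResult",
    "DegenerateFitError",
    "fit_unimodal",
    "fit_mixture_em",
    "rank_models",
    "n_parameters",
]

_WEIGHT_FLOOR = 1e-6
_SPREAD_FLOOR = 1e-8


class DegenerateFitError(RuntimeError):
    """Every EM restart collapsed a component; no usable mixture fit."""


@dataclass(frozen=True)
class FitResult:
    """A fitted parametric hypothesis with its total data log-likelihood."""

    spec: MixtureSpec
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: Optional[tuple[float, ...]] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.spec.family,
                "weights": list(self.spec.weights),
                "components": [list(c) for c in self.spec.components],
                "loglik": self.loglik,
                "n_iter": self.n_iter,
                "converged": self.converged,
            }
        )


def n_parameters(spec: MixtureSpec) -> int:
    """Free parameters: 2 per component plus k-1 mixture weights."""
    return 2 * spec.k + (spec.k - 1)


def _validate_values(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("need a vector of at least 3 values")
    if np.any(values <= 0):
        raise ValueError("all concentrations must be strictly positive")
    if np.unique(values).size < 3:
        raise ValueError("need at least 3 distinct values (degenerate spread)")
    return values


def _loglik(values: np.ndarray, spec: MixtureSpec) -> float:
    return float(np.sum(spec.logpdf(values)))


def fit_unimodal(values, family: str) -> FitResult:
    """ML fit of a single lognormal, gamma or Weibull distribution."""
    values = _validate_values(values)
    if family == "lognormal":
        logs = np.log(values)
        mu = float(logs.mean())
        sigma = float(np.sqrt(np.mean((logs - mu) ** 2)))
        if sigma < _SPREAD_FLOOR:
            raise ValueError("degenerate spread: sigma estimate is zero")
        spec = MixtureSpec("lognormal", (1.0,), ((mu, sigma),))
        return FitResult(spec, _loglik(values, spec), n_iter=1, converged=True)
    if family == "gamma":
        shape, _, scale = stats.gamma.fit(values, floc=0)
        spec = MixtureSpec("gamma", (1.0,), ((float(shape), float(scale)),))
    elif family == "weibull":
        shape, _, scale = stats.weibull_min.fit(values, floc=0)
        spec = MixtureSpec("weibull", (1.0,), ((float(shape), float(scale)),))
    else:
        raise ValueError(f"unknown family {family!r}")
    ll = _loglik(values, spec)
    converged = bool(np.isfinite(ll))
    if not converged:
        raise RuntimeError(f"unimodal {family} fit did not converge (loglik not finite)")
    return FitResult(spec, ll, n_iter=1, converged=True)


# ---------------------------------------------------------------------------
# weighted component ML updates for the EM M-step


def _weighted_lognormal_ml(y: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    w = r.sum()
    logs = np.log(y)
    mu = float((r * logs).sum() / w)
    sigma = float(np.sqrt((r * (logs - mu) ** 2).sum() / w))
    return mu, sigma


def _weighted_gamma_ml(y: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    w = r.sum()
    mw = (r * y).sum() / w
    mlog = (r * np.log(y)).sum() / w
    a = np.log(mw) - mlog  # >= 0 by Jensen
    if a < 1e-12:
        raise FloatingPointError("degenerate gamma component")
    # standard starting approximation, then solve log k - digamma(k) = a
    k0 = (3.0 - a + np.sqrt((a - 3.0) ** 2 + 24.0 * a)) / (12.0 * a)
    f = lambda k: np.log(k) - special.digamma(k) - a
    lo, hi = k0 / 16.0, k0 * 16.0
    while f(lo) < 0:
        lo /= 8.0
    while f(hi) > 0:
        hi *= 8.0
    shape = float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))
    return shape, float(mw / shape)


def _weighted_weibull_ml(y: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    logr = np.log(np.maximum(r, 1e-300))
    ly = np.log(y)
    w = r.sum()
    target = (r * ly).sum() / w

    def g(c: float) -> float:
        t = logr + c * ly
        tmax = t.max()
        e = np.exp(t - tmax)
        return float((e * ly).sum() / e.sum() - 1.0 / c - target)

    lo, hi = 1e-2, 8.0
    while g(hi) < 0 and hi < 1e4:
        hi *= 2.0
    while g(lo) > 0 and lo > 1e-8:
        lo /= 2.0
    shape = float(optimize.brentq(g, lo, hi, xtol=1e-12))
    t = logr + shape * ly
    scale = float(np.exp((special.logsumexp(t) - np.log(w)) / shape))
    return shape, scale


_M_STEP = {
    "lognormal": _weighted_lognormal_ml,
    "gamma": _weighted_gamma_ml,
    "weibull": _weighted_weibull_ml,
}


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _component_logpdf_matrix(
    values: np.ndarray, logs: np.ndarray, family: str,
    components: Sequence[tuple[float, float]],
) -> np.ndarray:
    # closed-form log densities; scipy dist objects are too slow inside EM
    cols = []
    for a, b in components:
        if family == "lognormal":
            cols.append(-logs - np.log(b) - _LOG_SQRT_2PI - (logs - a) ** 2 / (2.0 * b**2))
        elif family == "gamma":
            cols.append((a - 1.0) * logs - values / b - special.gammaln(a) - a * np.log(b))
        else:  # weibull
            z = values / b
            cols.append(np.log(a / b) + (a - 1.0) * (logs - np.log(b)) - z**a)
    return np.stack(cols, axis=1)


def _em_once(
    values: np.ndarray,
    init: MixtureSpec,
    tol: float,
    max_iter: int,
) -> FitResult:
    family = init.family
    weights = np.asarray(init.weights, dtype=float)
    components = list(init.components)
    logs = np.log(values)
    trace: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        logp = _component_logpdf_matrix(values, logs, family, components) + np.log(weights)
        norm = special.logsumexp(logp, axis=1)
        ll = float(norm.sum())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood in EM")
        trace.append(ll)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-12)
            if rel < tol:
                converged = True
                break
        resp = np.exp(logp - norm[:, None])
        weights = resp.mean(axis=0)
        if np.any(weights < _WEIGHT_FLOOR):
            raise FloatingPointError("component weight collapsed")
        new_components = []
        for j in range(len(components)):
            a, b = _M_STEP[family](values, resp[:, j])
            if family == "lognormal" and b < _SPREAD_FLOOR:
                raise FloatingPointError("component spread underflow")
            if family != "lognormal" and (a < _SPREAD_FLOOR or b < 1e-300):
                raise FloatingPointError("component parameter underflow")
            new_components.append((a, b))
        components = new_components
    spec = MixtureSpec(family, tuple(weights), tuple(components))
    return FitResult(spec, trace[-1], n_iter=len(trace), converged=converged,
                     loglik_trace=tuple(trace))


def _split_init(values: np.ndarray, family: str, q: float) -> Optional[MixtureSpec]:
    cut = float(np.quantile(values, q))
    lower = values[values <= cut]
    upper = values[values > cut]
    if np.unique(lower).size < 3 or np.unique(upper).size < 3:
        return None
    try:
        f_lo = fit_unimodal(lower, family)
        f_hi = fit_unimodal(upper, family)
    except (ValueError, RuntimeError):
        return None
    w = lower.size / values.size
    return MixtureSpec(
        family,
        (w, 1.0 - w),
        (f_lo.spec.components[0], f_hi.spec.components[0]),
    )


def fit_mixture_em(
    values,
    family: str,
    k: int = 2,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> FitResult:
    """Best-of-restarts EM fit of a k-component mixture (k in {1, 2})."""
    values = _validate_values(values)
    if k == 1:
        return fit_unimodal(values, family)
    if k != 2:
        raise ValueError("only k in {1, 2} is supported")

    unimodal = fit_unimodal(values, family)
    rng = np.random.default_rng(seed)
    inits: list[MixtureSpec] = []
    median_split = _split_init(values, family, 0.5)
    if median_split is not None:
        inits.append(median_split)
    # tied start: EM is stationary at the unimodal solution, guaranteeing
    # loglik(mixture) >= loglik(unimodal)
    inits.append(
        MixtureSpec(family, (0.5, 0.5),
                    (unimodal.spec.components[0], unimodal.spec.components[0]))
    )
    for q in rng.uniform(0.25, 0.75, size=n_restarts):
        init = _split_init(values, family, float(q))
        if init is not None:
            inits.append(init)

    best: Optional[FitResult] = None
    for init in inits:
        try:
            fit = _em_once(values, init, tol=tol, max_iter=max_iter)
        except FloatingPointError:
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise DegenerateFitError(
            f"all EM restarts collapsed a component for family {family!r}"
        )
    return best


def rank_models(fits: Sequence[FitResult]) -> list[FitResult]:
    """Order fits by log-likelihood, best first; ties go to fewer parameters."""
    return sorted(fits, key=lambda f: (-f.loglik, n_parameters(f.spec)))
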