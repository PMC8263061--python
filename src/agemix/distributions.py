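"""Candidate probability families for partner-age outcomes.

Five families are supported: normal, skew normal, gamma, beta and the
four-parameter sinh-arcsinh. The sinh-arcsinh is the centrepiece: it is
obtained by the monotone transformation ``S_{eps,delta}(x) =
sinh(eps + delta*asinh(x))`` of a standard normal variate, giving
independent control of location (mu), scale (sigma), skewness (eps) and
tail weight (delta). ``delta < 1`` produces heavier-than-normal tails;
``eps != 0`` produces asymmetry; ``eps = 0, delta = 1`` recovers the
normal exactly.

The sinh-arcsinh density, CDF, quantile function and sampler are authored
here in log-stable form; the remaining families defer to ``scipy.stats``.
All densities are evaluated on the log scale and out-of-domain points
return ``-inf`` rather than raising, so likelihood code stays total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import ndtr, ndtri

__all__ = [
    "SinhArcsinhParams",
    "SkewNormalParams",
    "GammaParams",
    "BetaParams",
    "NormalParams",
    "FAMILIES",
    "sinh_arcsinh_logpdf",
    "sinh_arcsinh_cdf",
    "sinh_arcsinh_quantile",
    "sinh_arcsinh_sample",
    "family_logpdf",
    "family_sample",
    "family_quantile",
]

FAMILIES = ("normal", "skew_normal", "gamma", "beta", "sinh_arcsinh")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class SinhArcsinhParams:
    """Location mu, scale sigma>0, skewness epsilon, tail weight delta>0."""

    mu: float
    sigma: float
    epsilon: float
    delta: float

    def __post_init__(self) -> None:
        vals = (self.mu, self.sigma, self.epsilon, self.delta)
        _require(all(np.isfinite(v) for v in vals), "parameters must be finite")
        _require(self.sigma > 0, "sigma must be positive")
        _require(self.delta > 0, "delta must be positive")


@dataclass(frozen=True)
class SkewNormalParams:
    """Location mu, scale sigma>0, slant epsilon."""

    mu: float
    sigma: float
    epsilon: float

    def __post_init__(self) -> None:
        _require(np.isfinite(self.mu) and np.isfinite(self.epsilon), "parameters must be finite")
        _require(self.sigma > 0, "sigma must be positive")


@dataclass(frozen=True)
class GammaParams:
    """Shape k>0 and scale theta>0; support is the positive reals."""

    k: float
    theta: float

    def __post_init__(self) -> None:
        _require(self.k > 0 and self.theta > 0, "k and theta must be positive")


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters alpha, beta > 0; support is the open unit interval."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _require(self.alpha > 0 and self.beta > 0, "alpha and beta must be positive")


@dataclass(frozen=True)
class NormalParams:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        _require(self.sigma > 0, "sigma must be positive")


# ---------------------------------------------------------------------------
# sinh-arcsinh core (array-valued parameters allowed; used by regression)
# ---------------------------------------------------------------------------

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _logcosh(w):
    # log cosh(w) = |w| + log1p(exp(-2|w|)) - log 2, stable for large |w|
    aw = np.abs(w)
    return aw + np.log1p(np.exp(-2.0 * aw)) - np.log(2.0)


def sas_logpdf(x, mu, sigma, epsilon, delta):
    """Vectorised sinh-arcsinh log-density; parameters may be arrays."""
    x, mu, sigma, epsilon, delta = np.broadcast_arrays(
        *map(np.asarray, (x, mu, sigma, epsilon, delta))
    )
    z = (x - mu) / sigma
    w = epsilon + delta * np.arcsinh(z)
    with np.errstate(over="ignore"):
        s2 = np.sinh(w) ** 2
    return (
        -np.log(sigma)
        - _LOG_SQRT_2PI
        + np.log(delta)
        + _logcosh(w)
        - 0.5 * np.log1p(z * z)
        - 0.5 * s2
    )


def sas_cdf(x, mu, sigma, epsilon, delta):
    """CDF via the normalising transform: Z = sinh(eps + delta*asinh(z))."""
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return ndtr(np.sinh(epsilon + delta * np.arcsinh(z)))


def sas_quantile(u, mu, sigma, epsilon, delta):
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly inside (0, 1)")
    return mu + sigma * np.sinh((np.arcsinh(ndtri(u)) - epsilon) / delta)


def sas_sample(n, mu, sigma, epsilon, delta, rng):
    z = rng.standard_normal(n)
    return mu + sigma * np.sinh((np.arcsinh(z) - epsilon) / delta)


def _check_sas(params: SinhArcsinhParams) -> SinhArcsinhParams:
    if not isinstance(params, SinhArcsinhParams):
        params = SinhArcsinhParams(*params)
    return params


def sinh_arcsinh_logpdf(x, params: SinhArcsinhParams):
    p = _check_sas(params)
    return sas_logpdf(x, p.mu, p.sigma, p.epsilon, p.delta)


def sinh_arcsinh_cdf(x, params: SinhArcsinhParams):
    p = _check_sas(params)
    return sas_cdf(x, p.mu, p.sigma, p.epsilon, p.delta)


def sinh_arcsinh_quantile(u, params: SinhArcsinhParams):
    p = _check_sas(params)
    return sas_quantile(u, p.mu, p.sigma, p.epsilon, p.delta)


def sinh_arcsinh_sample(n, params: SinhArcsinhParams, seed):
    if n < 1:
        raise ValueError("n must be at least 1")
    p = _check_sas(params)
    rng = np.random.default_rng(seed)
    return sas_sample(int(n), p.mu, p.sigma, p.epsilon, p.delta, rng)


# ---------------------------------------------------------------------------
# generic family dispatch
# ---------------------------------------------------------------------------


def _as_tuple(params):
    if hasattr(params, "__dataclass_fields__"):
        return tuple(getattr(params, f) for f in params.__dataclass_fields__)
    return tuple(params)


def family_logpdf(x, family: str, params):
    """Log-density of any supported family; out-of-domain x gives -inf.

    ``params`` may be the family's dataclass or a plain tuple in field
    order. Gamma takes (k, theta) with the scipy scale convention; beta
    takes (alpha, beta) on the open unit interval.
    """
    x = np.asarray(x, dtype=float)
    p = _as_tuple(params)
    if family == "normal":
        mu, sigma = p
        return stats.norm.logpdf(x, loc=mu, scale=sigma)
    if family == "skew_normal":
        mu, sigma, eps = p
        return stats.skewnorm.logpdf(x, eps, loc=mu, scale=sigma)
    if family == "gamma":
        k, theta = p
        with np.errstate(divide="ignore", invalid="ignore"):
            out = stats.gamma.logpdf(x, k, scale=theta)
        return np.where(x > 0, out, -np.inf)
    if family == "beta":
        a, b = p
        with np.errstate(divide="ignore", invalid="ignore"):
            out = stats.beta.logpdf(x, a, b)
        return np.where((x > 0) & (x < 1), out, -np.inf)
    if family == "sinh_arcsinh":
        mu, sigma, eps, delta = p
        return sas_logpdf(x, mu, sigma, eps, delta)
    raise ValueError(f"unknown family {family!r}")


def family_sample(family: str, params, size, rng):
    """Draw ``size`` variates; parameters may be arrays broadcasting to size."""
    p = _as_tuple(params)
    if family == "normal":
        mu, sigma = p
        return mu + sigma * rng.standard_normal(size)
    if family == "skew_normal":
        mu, sigma, eps = p
        return stats.skewnorm.rvs(eps, loc=mu, scale=sigma, size=size, random_state=rng)
    if family == "gamma":
        k, theta = p
        return rng.gamma(np.broadcast_to(k, size), np.broadcast_to(theta, size))
    if family == "beta":
        a, b = p
        return rng.beta(np.broadcast_to(a, size), np.broadcast_to(b, size))
    if family == "sinh_arcsinh":
        mu, sigma, eps, delta = p
        return sas_sample(size, mu, sigma, eps, delta, rng)
    raise ValueError(f"unknown family {family!r}")


def family_quantile(u, family: str, params):
    p = _as_tuple(params)
    if family == "normal":
        mu, sigma = p
        return stats.norm.ppf(u, loc=mu, scale=sigma)
    if family == "skew_normal":
        mu, sigma, eps = p
        return stats.skewnorm.ppf(u, eps, loc=mu, scale=sigma)
    if family == "gamma":
        k, theta = p
        return stats.gamma.ppf(u, k, scale=theta)
    if family == "beta":
        a, b = p
        return stats.beta.ppf(u, a, b)
    if family == "sinh_arcsinh":
        mu, sigma, eps, delta = p
        return sas_quantile(u, mu, sigma, eps, delta)
    raise ValueError(f"unknown family {family!r}")
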