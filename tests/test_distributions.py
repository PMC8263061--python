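"""Distribution correctness: normalisation, limits, inverses, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats
from scipy.optimize import brentq

from agemix.distributions import (
    BetaParams,
    GammaParams,
    NormalParams,
    SinhArcsinhParams,
    SkewNormalParams,
    family_logpdf,
    family_quantile,
    family_sample,
    sas_cdf,
    sas_logpdf,
    sas_quantile,
    sinh_arcsinh_cdf,
    sinh_arcsinh_logpdf,
    sinh_arcsinh_quantile,
    sinh_arcsinh_sample,
)

SAS_GRID = [
    (0.0, 1.0, 0.0, 1.0),
    (2.0, 3.0, 0.8, 0.5),
    (1.0, 2.0, -0.3, 1.4),
    (0.0, 1.0, 2.0, 0.25),
    (0.0, 1.0, -2.0, 4.0),
    (-1.0, 0.5, 2.0, 4.0),
]


def test_standard_normal_point_value():
    # eps=0, delta=1 collapses the transform: S(x)=x, C(x)=sqrt(1+x^2)
    assert sinh_arcsinh_logpdf(0.0, SinhArcsinhParams(0, 1, 0, 1)) == pytest.approx(
        math.log(1 / math.sqrt(2 * math.pi)), abs=1e-14
    )


def test_normal_limit_uniform_on_interval():
    x = np.linspace(-10, 10, 2001)
    err = np.abs(sas_logpdf(x, 1.5, 2.5, 0.0, 1.0) - stats.norm.logpdf(x, 1.5, 2.5))
    assert np.max(err) < 1e-12


@pytest.mark.parametrize("mu,sigma,eps,delta", SAS_GRID)
def test_density_integrates_to_one(mu, sigma, eps, delta):
    lo = sas_quantile(1e-12, mu, sigma, eps, delta)
    hi = sas_quantile(1 - 1e-12, mu, sigma, eps, delta)
    val, _ = integrate.quad(
        lambda x: np.exp(sas_logpdf(x, mu, sigma, eps, delta)), lo, hi, limit=300
    )
    assert val == pytest.approx(1.0, abs=1e-6)


def test_logpdf_matches_direct_formula():
    # independent evaluation of the closed-form density (no log-space tricks)
    params = SinhArcsinhParams(1.0, 2.0, -0.3, 1.4)
    for x in [-3.0, 0.2, float(sinh_arcsinh_quantile(0.5, params)), 4.7]:
        z = (x - params.mu) / params.sigma
        w = params.epsilon + params.delta * math.asinh(z)
        direct = (
            (1 / (params.sigma * math.sqrt(2 * math.pi)))
            * params.delta
            * math.cosh(w)
            / math.sqrt(1 + z**2)
            * math.exp(-math.sinh(w) ** 2 / 2)
        )
        assert sinh_arcsinh_logpdf(x, params) == pytest.approx(math.log(direct), rel=1e-12)


def test_logpdf_finite_at_extreme_arguments():
    p = SinhArcsinhParams(0, 1, 0.5, 4.0)
    vals = sinh_arcsinh_logpdf(np.array([-1e6, -50.0, 50.0, 1e6]), p)
    assert np.all(np.isfinite(vals))


def test_cdf_median_and_normal_limit():
    for delta in (0.5, 1.0, 2.0):
        assert sinh_arcsinh_cdf(3.0, SinhArcsinhParams(3.0, 2.0, 0.0, delta)) == pytest.approx(0.5)
    assert sinh_arcsinh_cdf(1.0, SinhArcsinhParams(0, 1, 0, 1)) == pytest.approx(
        stats.norm.cdf(1.0), abs=1e-12
    )


def test_cdf_quantile_roundtrip():
    params = SinhArcsinhParams(0, 1, 1.0, 0.7)
    u = np.linspace(0.01, 0.99, 99)
    assert np.max(np.abs(sinh_arcsinh_cdf(sinh_arcsinh_quantile(u, params), params) - u)) < 1e-10


def test_quantile_examples():
    assert sinh_arcsinh_quantile(0.5, SinhArcsinhParams(2.5, 3, 0, 0.8)) == pytest.approx(2.5)
    assert sinh_arcsinh_quantile(0.975, SinhArcsinhParams(0, 1, 0, 1)) == pytest.approx(
        1.959964, abs=1e-6
    )


def test_quantile_agrees_with_rootfinding():
    rng = np.random.default_rng(3)
    worst = 0.0
    for _ in range(20):
        mu, sigma = rng.normal(0, 2), rng.uniform(0.3, 3)
        eps, delta = rng.normal(0, 1), rng.uniform(0.4, 2.5)
        u = rng.uniform(0.05, 0.95)
        q = sas_quantile(u, mu, sigma, eps, delta)
        root = brentq(
            lambda x: sas_cdf(x, mu, sigma, eps, delta) - u, q - 50, q + 50, xtol=1e-12
        )
        worst = max(worst, abs(q - root))
    assert worst < 1e-8


def test_cdf_strictly_increasing():
    # grid kept inside the float-representable range of the CDF tails
    x = np.linspace(-8, 8, 200)
    c = sas_cdf(x, 0, 1, 1.5, 0.4)
    assert np.all(np.diff(c) > 0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    u=st.floats(0.01, 0.99),
    eps=st.floats(-2, 2),
    delta=st.floats(0.3, 3),
)
def test_roundtrip_property(u, eps, delta):
    q = sas_quantile(u, 0.0, 1.0, eps, delta)
    assert sas_cdf(q, 0.0, 1.0, eps, delta) == pytest.approx(u, abs=1e-9)


def test_sampler_reproducible_and_normal_limit():
    p = SinhArcsinhParams(0, 1, 0, 1)
    x1 = sinh_arcsinh_sample(10**5, p, seed=11)
    x2 = sinh_arcsinh_sample(10**5, p, seed=11)
    assert np.array_equal(x1, x2)
    assert stats.kstest(x1, "norm").statistic < 0.01


def test_sampler_matches_quantiles():
    p = SinhArcsinhParams(0, 1, 0.5, 0.6)
    x = sinh_arcsinh_sample(10**5, p, seed=5)
    emp = np.quantile(x, [0.1, 0.5, 0.9])
    theo = sinh_arcsinh_quantile(np.array([0.1, 0.5, 0.9]), p)
    assert np.max(np.abs(emp - theo)) < 0.05


@pytest.mark.parametrize(
    "family,params",
    [
        ("normal", NormalParams(1.0, 2.0)),
        ("skew_normal", SkewNormalParams(0.5, 1.5, 2.0)),
        ("gamma", GammaParams(2.0, 3.0)),
        ("beta", BetaParams(2.5, 1.5)),
        ("sinh_arcsinh", SinhArcsinhParams(0.0, 1.0, 0.5, 0.6)),
    ],
)
def test_all_family_samplers_match_analytic_cdf(family, params):
    rng = np.random.default_rng(17)
    x = family_sample(family, params, 10**5, rng)
    d = stats.kstest(x, lambda q: _cdf(family, q, params)).statistic
    assert d < 0.01


def _cdf(family, x, params):
    if family == "normal":
        return stats.norm.cdf(x, params.mu, params.sigma)
    if family == "skew_normal":
        return stats.skewnorm.cdf(x, params.epsilon, loc=params.mu, scale=params.sigma)
    if family == "gamma":
        return stats.gamma.cdf(x, params.k, scale=params.theta)
    if family == "beta":
        return stats.beta.cdf(x, params.alpha, params.beta)
    return sas_cdf(x, params.mu, params.sigma, params.epsilon, params.delta)


def test_skew_normal_reduces_to_normal():
    x = np.linspace(-4, 6, 50)
    a = family_logpdf(x, "skew_normal", SkewNormalParams(1.0, 2.0, 0.0))
    b = family_logpdf(x, "normal", NormalParams(1.0, 2.0))
    assert np.allclose(a, b, atol=1e-12)


def test_gamma_logpdf_at_mean():
    # density at x = k*theta for k=2, theta=3: (1/(Gamma(2) 3^2)) * 6 * e^-2
    expect = math.log(6.0 / 9.0) - 2.0
    assert family_logpdf(6.0, "gamma", GammaParams(2, 3)) == pytest.approx(expect, rel=1e-12)


def test_beta_density_normalised():
    val, _ = integrate.quad(
        lambda x: np.exp(family_logpdf(x, "beta", BetaParams(2.5, 1.5))), 0, 1
    )
    assert val == pytest.approx(1.0, abs=1e-6)


def test_out_of_domain_gives_neg_inf_not_error():
    assert family_logpdf(-1.0, "gamma", GammaParams(2, 3)) == -np.inf
    assert family_logpdf(1.5, "beta", BetaParams(2, 2)) == -np.inf
    assert family_logpdf(0.0, "beta", BetaParams(2, 2)) == -np.inf


def test_tail_mass_decreases_with_delta():
    # smaller delta = heavier tails: P(|X| > 5) strictly decreasing in delta
    masses = [
        1 - sas_cdf(5.0, 0, 1, 0, d) + sas_cdf(-5.0, 0, 1, 0, d) for d in (0.5, 1.0, 2.0)
    ]
    assert masses[0] > masses[1] > masses[2]


def test_skewness_sign_flips_with_epsilon():
    # with epsilon inside the transform, positive epsilon skews mass left
    rng = np.random.default_rng(0)
    s_pos = stats.skew(family_sample("sinh_arcsinh", (0, 1, 1.0, 1.0), 10**5, rng))
    s_neg = stats.skew(family_sample("sinh_arcsinh", (0, 1, -1.0, 1.0), 10**5, rng))
    assert s_pos < -0.5 and s_neg > 0.5


def test_parameter_validation():
    with pytest.raises(ValueError):
        SinhArcsinhParams(0, -1, 0, 1)
    with pytest.raises(ValueError):
        SinhArcsinhParams(0, 1, 0, 0)
    with pytest.raises(ValueError):
        GammaParams(0, 1)
    with pytest.raises(ValueError):
        sinh_arcsinh_quantile(1.0, SinhArcsinhParams(0, 1, 0, 1))
    with pytest.raises(ValueError):
        sinh_arcsinh_sample(0, SinhArcsinhParams(0, 1, 0, 1), seed=0)


def test_quantile_consistency_across_families():
    u = np.array([0.25, 0.5, 0.75])
    for family, params in [
        ("gamma", GammaParams(2.0, 3.0)),
        ("beta", BetaParams(2.5, 1.5)),
        ("sinh_arcsinh", SinhArcsinhParams(1, 2, 0.3, 0.8)),
    ]:
        q = family_quantile(u, family, params)
        assert np.allclose(_cdf(family, q, params), u, atol=1e-9)
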