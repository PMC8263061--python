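"""Distributional regression: designs, likelihood, priors, fitting."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import approx_fprime

import agemix.regression as reg
from agemix.distributions import family_logpdf
from agemix.synthetic_data import default_scenarios, generate


def _records(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "respondent_age": rng.integers(15, 65, n),
            "respondent_sex": rng.integers(0, 2, n),
            "partner_age": rng.integers(16, 70, n).astype(float),
        }
    )


class TestDesignMatrices:
    def test_constant_is_column_of_ones(self):
        X = reg.build_design_matrix(_records(3), "constant")
        assert X.shape == (3, 1) and np.all(X == 1.0)

    def test_interaction_has_four_columns(self):
        recs = _records(10)
        X = reg.build_design_matrix(recs, "age_sex_interaction")
        assert X.shape == (10, 4)
        a_std = (recs["respondent_age"] - 40) / 10
        assert np.allclose(X[:, 1], a_std)
        assert np.allclose(X[:, 3], a_std * recs["respondent_sex"])

    def test_additive_has_three_columns(self):
        assert reg.build_design_matrix(_records(6), "age_sex_additive").shape == (6, 3)

    def test_spline_partition_of_unity_and_column_count(self):
        recs = _records(200, seed=1)
        X = reg.build_design_matrix(recs, ("sex_specific_spline", 5))
        # 2 per-sex intercepts + 2 * (5 interior knots + order 4) bases
        assert X.shape[1] == 2 * (5 + 4) + 2
        basis_sum = X[:, 2:].sum(axis=1)
        assert np.allclose(basis_sum, 1.0, atol=1e-10)

    def test_spline_prediction_uses_frozen_knots(self):
        recs = _records(150, seed=2)
        info = reg.resolve_design(recs, ("sex_specific_spline", 5))
        X1 = info.matrix([25, 40], [0, 1])
        X2 = info.matrix([25, 40], [0, 1])
        assert np.array_equal(X1, X2)

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            reg.build_design_matrix(_records(0), "constant")


class TestTable2Specs:
    def test_conventional(self):
        spec = reg.make_table2_spec("Conventional")
        assert spec.design["mu"] == "age_sex_interaction"
        assert all(spec.design[p] == "constant" for p in ("sigma", "epsilon", "delta"))
        assert spec.family == "sinh_arcsinh" and spec.outcome == "log_ratio"

    def test_distributional_1_and_3(self):
        d1 = reg.make_table2_spec("Distributional 1")
        assert d1.design["mu"] == "age_sex_interaction"
        assert all(d1.design[p] == "age_sex_additive" for p in ("sigma", "epsilon", "delta"))
        d3 = reg.make_table2_spec("Distributional 3")
        assert d3.design["mu"] == ("sex_specific_spline", 5)
        assert all(d3.design[p] == "age_sex_interaction" for p in ("sigma", "epsilon", "delta"))

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            reg.make_table2_spec("Distributional 9")

    def test_spec_dict_roundtrip(self):
        spec = reg.make_table2_spec("Distributional 4")
        assert reg.ModelSpec.from_dict(spec.to_dict()) == spec


class TestLogPrior:
    def test_at_zero(self):
        k = 7
        expect = k * math.log(1 / (5 * math.sqrt(2 * math.pi)))
        assert reg.log_prior(np.zeros(k)) == pytest.approx(expect)

    def test_one_sd_displacement(self):
        base = reg.log_prior(np.zeros(4))
        moved = np.zeros(4)
        moved[2] = 5.0
        assert reg.log_prior(moved) == pytest.approx(base - 0.5)

    def test_matches_scalar_normal_sum(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 3, size=13)
        assert reg.log_prior(v) == pytest.approx(float(np.sum(stats.norm.logpdf(v, 0, 5))))


class TestLogLikelihood:
    def test_conventional_collapses_to_plain_normal(self):
        recs = _records(60, seed=3)
        spec = reg.make_table2_spec("Conventional")
        coefs = {
            "mu": np.array([0.1, 0.0, 0.0, 0.0]),
            "sigma": np.array([math.log(0.3)]),
            "epsilon": np.array([0.0]),
            "delta": np.array([0.0]),  # delta = 1 -> sinh-arcsinh is normal
        }
        ll = reg.log_likelihood(recs, spec, coefs)
        y = np.log(recs["partner_age"] / recs["respondent_age"])
        expect = stats.norm.logpdf(y, 0.1, 0.3) - np.log(recs["partner_age"])
        assert np.allclose(ll, expect, atol=1e-10)

    def test_delta_intercept_rescales_sigma(self):
        recs = _records(20, seed=4)
        spec = reg.make_table2_spec("Conventional")
        infos = {p: reg.resolve_design(recs, spec.design[p]) for p in spec.param_names}
        base = {
            "mu": np.zeros((1, 4)),
            "sigma": np.array([[math.log(0.2)]]),
            "epsilon": np.zeros((1, 1)),
            "delta": np.zeros((1, 1)),
        }
        fr = reg.FitResult(spec, infos, base, {}, np.zeros((1, 1)), recs, {})
        nat1 = fr.linear_predictors(recs["respondent_age"], recs["respondent_sex"])
        shifted = dict(base, delta=np.array([[math.log(2.0)]]))
        fr2 = reg.FitResult(spec, infos, shifted, {}, np.zeros((1, 1)), recs, {})
        nat2 = fr2.linear_predictors(recs["respondent_age"], recs["respondent_sex"])
        assert np.allclose(nat2["sigma"], 2.0 * nat1["sigma"])
        assert np.allclose(nat2["sigma_star"], nat1["sigma_star"])

    def test_matches_scalar_bruteforce(self, tiny_records):
        spec = reg.make_table2_spec("Distributional 2")
        rng = np.random.default_rng(11)
        coefs = {p: rng.normal(0, 0.1, 4) for p in spec.param_names}
        coefs["mu"][0] = 0.05
        coefs["sigma"][0] = math.log(0.25)
        ll = reg.log_likelihood(tiny_records, spec, coefs)
        for i, row in tiny_records.iterrows():
            a, s, p = row["respondent_age"], row["respondent_sex"], row["partner_age"]
            x = np.array([1.0, (a - 40) / 10, s, (a - 40) / 10 * s])
            mu = coefs["mu"] @ x
            sig_star = math.exp(coefs["sigma"] @ x)
            eps = coefs["epsilon"] @ x
            delta = math.exp(coefs["delta"] @ x)
            y = math.log(p / a)
            expect = family_logpdf(
                y, "sinh_arcsinh", (mu, sig_star * delta, eps, delta)
            ) - math.log(p)
            assert ll[i] == pytest.approx(float(expect), rel=1e-10)

    def test_nesting_distributional1_reproduces_conventional(self, tiny_records):
        conv = reg.make_table2_spec("Conventional")
        d1 = reg.make_table2_spec("Distributional 1")
        c_conv = {
            "mu": np.array([0.05, -0.02, 0.08, -0.01]),
            "sigma": np.array([math.log(0.2)]),
            "epsilon": np.array([0.1]),
            "delta": np.array([0.05]),
        }
        c_d1 = dict(
            c_conv,
            sigma=np.array([math.log(0.2), 0.0, 0.0]),
            epsilon=np.array([0.1, 0.0, 0.0]),
            delta=np.array([0.05, 0.0, 0.0]),
        )
        assert np.allclose(
            reg.log_likelihood(tiny_records, conv, c_conv),
            reg.log_likelihood(tiny_records, d1, c_d1),
            atol=1e-12,
        )


def test_analytic_gradient_matches_numeric(small_linear_records):
    recs = small_linear_records.head(300)
    spec = reg.make_table2_spec("Distributional 2")
    infos = {p: reg.resolve_design(recs, spec.design[p]) for p in spec.param_names}
    sizes = {p: infos[p].n_columns for p in spec.param_names}

    def unflatten(flat):
        out, i = {}, 0
        for p in spec.param_names:
            out[p] = flat[i : i + sizes[p]]
            i += sizes[p]
        return out

    def neg_log_post(flat):
        ll = reg.log_likelihood(recs, spec, unflatten(flat), infos)
        return -(float(np.sum(ll)) + reg.log_prior(flat))

    rng = np.random.default_rng(21)
    for _ in range(3):
        x = rng.normal(0, 0.05, sum(sizes.values()))
        x[4] = math.log(0.3)  # sigma intercept
        num = approx_fprime(x, neg_log_post, 1e-7)
        blocks = unflatten(x)
        a, s = recs["respondent_age"].to_numpy(float), recs["respondent_sex"].to_numpy()
        X = {p: infos[p].matrix(a, s) for p in spec.param_names}
        nat = reg._natural_params(spec, blocks, X)
        y, _ = reg._modelled_variable(recs, spec)
        g = reg._grad_blocks(spec, y, nat, X)
        ana = -(np.concatenate([g[p] for p in spec.param_names]) - x / 25.0)
        assert np.allclose(ana, num, rtol=1e-5, atol=1e-4)


class TestFit:
    def test_same_seed_identical_draws(self, small_linear_records):
        recs = small_linear_records.head(400)
        spec = reg.make_table2_spec("Conventional")
        f1 = reg.fit(recs, spec, seed=9)
        f2 = reg.fit(recs, spec, seed=9)
        for p in spec.param_names:
            assert np.array_equal(f1.coef_draws[p], f2.coef_draws[p])

    def test_well_specified_null_normal(self):
        rng = np.random.default_rng(2)
        n = 500
        recs = pd.DataFrame(
            {
                "respondent_age": rng.integers(15, 65, n),
                "respondent_sex": rng.integers(0, 2, n),
                "partner_age": np.full(n, 30.0),
            }
        )
        # model y = N(0,1) noise via the age_difference outcome
        recs["partner_age"] = recs["respondent_age"] + rng.normal(0, 1, n)
        spec = reg.ModelSpec(
            family="normal",
            outcome="age_difference",
            design={"mu": "constant", "sigma": "constant"},
        )
        fr = reg.fit(recs, spec, seed=1)
        mu_draws = fr.coef_draws["mu"][:, 0]
        assert abs(np.mean(mu_draws)) < 3 * np.std(mu_draws) + 0.05

    def test_insufficient_records_error(self):
        with pytest.raises(ValueError):
            reg.fit(_records(3), reg.make_table2_spec("Conventional"))

    def test_distributional_beats_conventional_in_sample(self):
        # truth has age-varying scale: any distributional spec must fit better
        cfg = dataclasses.replace(
            default_scenarios()["linear_distributional"], n_respondents=800
        )
        for seed in (0, 1, 2):
            recs, _ = generate(cfg, seed=seed)
            conv = reg.fit(recs, reg.make_table2_spec("Conventional"), seed=seed)
            conv_ll = np.mean(reg.log_likelihood(recs, conv.spec, conv.map_coefs))
            for name in ("Distributional 1", "Distributional 2"):
                dist = reg.fit(recs, reg.make_table2_spec(name), seed=seed)
                dist_ll = np.mean(reg.log_likelihood(recs, dist.spec, dist.map_coefs))
                assert dist_ll > conv_ll

    def test_mcmc_engine_runs_and_is_seeded(self, small_linear_records):
        recs = small_linear_records.head(300)
        spec = reg.ModelSpec(
            family="normal",
            outcome="log_ratio",
            design={"mu": "constant", "sigma": "constant"},
        )
        f1 = reg.fit(recs, spec, engine="mcmc", draws=200, seed=4, mcmc_steps=300, mcmc_burn=200)
        f2 = reg.fit(recs, spec, engine="mcmc", draws=200, seed=4, mcmc_steps=300, mcmc_burn=200)
        assert np.array_equal(f1.coef_draws["mu"], f2.coef_draws["mu"])
        assert f1.diagnostics["mean_acceptance_fraction"] > 0.05


class TestPosteriorPredict:
    def _degenerate_fit(self, m=0.1, s=0.25, draws=200):
        recs = _records(30, seed=8)
        spec = reg.ModelSpec(
            family="normal",
            outcome="log_ratio",
            design={"mu": "constant", "sigma": "constant"},
        )
        infos = {p: reg.resolve_design(recs, spec.design[p]) for p in spec.param_names}
        coef = {
            "mu": np.full((draws, 1), m),
            "sigma": np.full((draws, 1), math.log(s)),
        }
        return reg.FitResult(spec, infos, coef, {}, np.zeros((draws, 30)), recs, {})

    def test_predictive_matches_lognormal_quantiles(self):
        m, s = 0.1, 0.25
        fr = self._degenerate_fit(m, s)
        ages = np.full(200, 30.0)
        pred = reg.posterior_predict(fr, ages, np.zeros(200, int), draws_per_obs=500, seed=3)
        q_emp = np.quantile(pred.ravel(), [0.1, 0.5, 0.9])
        q_true = 30.0 * np.exp(stats.norm.ppf([0.1, 0.5, 0.9], m, s))
        assert np.allclose(q_emp, q_true, rtol=0.02)

    def test_log_ratio_inversion_is_exact(self):
        fr = self._degenerate_fit(0.0, 1e-9)
        ages = np.array([20.0, 40.0, 60.0])
        pred = reg.posterior_predict(fr, ages, np.array([0, 1, 0]), draws_per_obs=5, seed=0)
        assert np.allclose(pred, ages[:, None], rtol=1e-6)

    def test_extrapolation_warns(self):
        fr = self._degenerate_fit()
        with pytest.warns(UserWarning):
            reg.posterior_predict(fr, np.array([70.0]), np.array([1]), 2, seed=0)

    def test_predictive_mean_stable_across_seeds(self):
        fr = self._degenerate_fit(0.1, 0.25)
        ages = np.full(100, 35.0)
        means = [
            reg.posterior_predict(fr, ages, np.ones(100, int), draws_per_obs=200, seed=s).mean()
            for s in (1, 2)
        ]
        assert abs(means[0] - means[1]) < 0.15
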