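# agemix

Distributional regression for self-reported sexual partner age
distributions.

## The problem

The ages of people's sexual partners — reported in household surveys
(DHS) and population cohorts — determine how sexually transmitted
infections, HIV above all, move between generations. These
distributions are awkward: variance, skewness and tail weight all
change with the respondent's age and sex, and conventional regression,
which models only the mean, flattens exactly the features that matter
for transmission. `agemix` is for epidemiologists and biostatisticians
who need full conditional partner-age distributions with quantified
uncertainty.

## What it does

* **Distributions** — the four-parameter sinh-arcsinh family
  (location μ, scale σ, skewness ϵ, tail weight δ; the transform
  S(z) = sinh(ϵ + δ asinh(z)) of a standard normal), with stable
  log-density, CDF, quantile function and sampler, alongside normal,
  skew normal, gamma and beta alternatives.
* **Outcomes** — four parametrisations of partner age p given
  respondent age a (p, p − a, log p, log(p/a)) with exact inverses and
  log-Jacobians, so models of different outcomes are comparable on the
  common partner-age scale.
* **Regression** — Bayesian distributional regression in which all
  four sinh-arcsinh parameters get their own design matrices:

      y_i = log(p_i/a_i) ~ sinh-arcsinh(μ_i, σ_i, ϵ_i, δ_i)
      μ_i = β_μ·X_i^μ   log σ*_i = β_σ·X_i^σ
      ϵ_i = β_ϵ·X_i^ϵ   log δ_i = β_δ·X_i^δ,   σ_i = σ*_i δ_i

  with N(0, 5) priors, five benchmark design configurations from
  conventional (constant higher-order parameters) to sex-specific
  B-spline curves for everything, MAP + curvature-matched Laplace
  inference (HMC/ensemble MCMC optional), and posterior-predictive
  simulation.
* **Comparison** — ELPD via PSIS-LOO (with Pareto-k diagnostics,
  paired difference SEs and a 2-SE significance rule) and QQ RMSE: the
  root-mean-squared gap, in years, between observed and
  posterior-predictive deciles by sex and five-year age bin.
* **Synthetic data** — a generator that runs the model forwards with
  known truth curves, multi-partner respondents, integer-year
  reporting and optional heaping on multiples of five, so the whole
  pipeline is testable without access to restricted survey data.

## Worked example

```python
import dataclasses
from agemix import default_scenarios, generate, make_table2_spec, fit, elpd

cfg = dataclasses.replace(default_scenarios()["heavy_tail"], n_respondents=2000)
records, truth = generate(cfg, seed=1)
print(len(records))                      # 4524 partnerships

from agemix.regression import intercept_only_spec
sas = fit(records, intercept_only_spec("sinh_arcsinh", "log_ratio"), seed=0)
norm = fit(records, intercept_only_spec("normal", "log_ratio"), seed=0)
print(round(elpd(sas.pointwise).elpd, 1))   # -16561.4
print(round(elpd(norm.pointwise).elpd, 1))  # -16871.8
```

The truth here has tail weight δ = 0.5 (much heavier than normal
tails), and the sinh-arcsinh fit beats the normal fit by ~310 ELPD
units: each reported partnership is, on average, noticeably more
probable under the model that can widen its tails. The fitted δ is
recoverable from `sas.coef_draws["delta"]` (posterior of log δ).

From the shell, the same experiments run end to end on synthetic data:

    agemix simulate --scenario spline_shaped --seed 1 --outdir out
    agemix compare-distributions --seed 1 --outdir out
    agemix evaluate-regression --seed 1 --outdir out
    agemix report --outdir out

`compare-distributions` fits all 14 viable distribution-outcome
combinations to every sex × five-year-age-bin subset of each dataset
(504 fits for three datasets) and tabulates Jacobian-adjusted ELPD and
QQ RMSE per family; `evaluate-regression` fits the five benchmark
design configurations and ranks them with 2-SE flags, exporting fitted
parameter trajectories over age and sex.

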