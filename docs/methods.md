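# Methods

## The problem

Self-reported sexual partner ages from household surveys and
population cohorts drive estimates of age-mixing — who partners with
whom across ages — which in turn shapes models of HIV and other STI
transmission. These data are heavily non-Gaussian: variance, skewness
and tail weight all change with the respondent's age and sex, and
reports cluster ("heap") on multiples of five. `agemix` models the full
conditional distribution of partner age given respondent age and sex,
rather than just its mean.

## The sinh-arcsinh family

The centrepiece is the four-parameter sinh-arcsinh distribution. With
`z = (x - mu) / sigma`, `S(z) = sinh(eps + delta * asinh(z))` and
`C(z) = cosh(eps + delta * asinh(z))`, the density is

    f(x) = (1 / (sigma sqrt(2 pi))) * delta * C(z) / sqrt(1 + z^2)
           * exp(-S(z)^2 / 2)

Equivalently, `S((x - mu)/sigma)` is a standard normal variate, which
gives closed-form CDF, quantile function and sampler. `eps = 0,
delta = 1` recovers the normal exactly; `delta < 1` gives heavier
tails; `eps != 0` gives asymmetry. We adopt the "eps inside"
parametrisation literally; under it a **positive** eps skews mass to
the **left** (negative sample skewness), which our tests pin down,
because published variants of the family differ in this sign
convention. All density work is done in log space
(`log cosh(w) = |w| + log1p(exp(-2|w|)) - log 2`) so that large `|w|`
cannot overflow.

Alternatives compared: normal, skew normal (slant eps), gamma (shape,
scale) and beta. Gamma is always right-skewed while men's reported
partner ages are left-skewed, so for male respondents partner ages are
reflected (`150 - p`) before a gamma fit; beta requires the unit
interval, so partner ages are scaled by fixed bounds 0 and 150. Both
transforms carry their Jacobians (the reflection's is 1, the scaling's
is 1/150) into any cross-family comparison.

## Outcomes and Jacobian-adjusted comparison

Four outcome parametrisations of partner age `p` given respondent age
`a` are supported: `p` itself, the age difference `p - a`, `log p`, and
the log-ratio `log(p / a)`. Models of different outcomes are compared
on the common partner-age scale by adding `log |dy/dp|` to each
log-density (for the log transforms this subtracts `log p`). The tests
verify the resulting invariance directly: a normal model of `log p`
and the corresponding lognormal model of `p` produce identical adjusted
ELPDs.

## Distributional regression

Every family parameter has its own linear predictor. For the
sinh-arcsinh log-ratio model:

    y_i ~ sinh-arcsinh(mu_i, sigma_i, eps_i, delta_i)
    mu_i = b_mu . X_mu_i          log sigma*_i = b_sig . X_sig_i
    eps_i = b_eps . X_eps_i       log delta_i  = b_del . X_del_i
    sigma_i = sigma*_i * delta_i

with independent N(0, 5) priors on every coefficient. The
`sigma = sigma* * delta` rescaling compensates for delta's effect on
the variance of the sinh-arcsinh variate, making `sigma*` interpretable
as spread; it is applied to the sinh-arcsinh family only, where the
model defines it (the other families have no tail-weight parameter to
couple to).

Five benchmark design configurations span conventional regression
(age-sex interaction for location, constants elsewhere) through fully
distributional models with per-sex spline curves for all four
parameters. Ages enter standardised by fixed constants,
`(age - 40) / 10`, so coefficients and priors mean the same thing
across datasets.

**Splines.** Sex-specific smooths use cubic B-splines with K = 5
interior knots at evenly spaced quantiles of the observed standardised
ages, plus per-sex intercept columns (2(K + 4) + 2 = 20 columns). This
is a fixed-knot, unpenalised basis chosen for reproducibility; a
penalised thin-plate smooth would differ in basis but spans comparable
low-rank smooths. The basis columns sum to one (partition of unity), so
they are collinear with the per-sex intercepts; the N(0, 5) prior keeps
the posterior proper along that ridge, and the ridge direction is
prediction-neutral. Knots are frozen at fit time and reused for
prediction; covariates outside the observed range are clamped to the
boundary basis values and flagged.

## Posterior computation

The fitting contract is "S posterior draws whose pointwise
log-likelihood matrix is exposed", not a particular sampler. Three
routes are provided:

* **MAP + curvature-matched Laplace (default).** L-BFGS finds the
  posterior mode using analytic gradients for the sinh-arcsinh and
  normal families (finite differences otherwise); the Hessian of the
  negative log posterior is formed by central differences of the
  gradient. Because the exact Hessian has every eigenvalue at least
  1/25 from the prior, eigenvalues below half that are treated as
  numerical noise and clipped. Each eigendirection is then probed at
  its ±1-sd scale and its curvature inflated where the local quadratic
  underestimates the drop — without this, draws of log-scale and
  tail-weight coefficients can overshoot into regions where the
  likelihood collapses. Draws are Gaussian at the mode with the
  resulting covariance.
* **Sampling-importance-resampling refinement (`sir=True`).** Four
  times the requested draws are proposed from the Laplace Gaussian,
  weighted by posterior/proposal, and resampled. This corrects the
  Gaussian's symmetry error and is recommended for fits with up to a
  few dozen coefficients; in high dimensions importance weights
  degenerate (the effective sample size diagnostic `sir_ess` is
  attached), so it is off by default.
* **MCMC (`engine="mcmc"`).** For families with analytic gradients,
  Hamiltonian Monte Carlo preconditioned by the Laplace
  eigendecomposition (dual-averaged step size, 0.8 acceptance target);
  for the others, an affine-invariant ensemble sampler. The HMC mixes
  well for low- and moderate-dimensional specifications; for the
  80-coefficient all-spline model the posterior has funnel-like
  geometry from the exponential links and step sizes become very
  small, so the Laplace route is the practical default there.

The Laplace approximation is exactly that — an approximation. Our
calibration experiments (the parameter-recovery study below) show that
for the 16-coefficient interaction model at ~5,000 observations its
95% intervals cover truth at close to nominal rates. For the
all-spline model the approximate draws sit systematically closer to
the mode than true posterior draws would; model rankings at survey
scale (~20,000 records) are insensitive to this, which is the regime
where the all-spline model is compared.

Every stochastic operation takes an explicit seed; identical seeds
byte-reproduce draws, predictions and pipeline outputs.

## Model comparison

**ELPD.** The expected log predictive density is estimated by
Pareto-smoothed importance-sampling leave-one-out (PSIS-LOO) from the
S x N pointwise matrix, with the standard generalised-Pareto smoothing
of the upper 20% of importance weights and per-observation Pareto-k
diagnostics (k > 0.7 raises a warning). WAIC is available as a cheap
cross-check and brute-force refit LOO as a test-scale oracle. The SE of
an ELPD is sqrt(N var(pointwise contributions)); pairwise model
differences use the paired per-observation contributions, and a model
is called significantly better when |delta| exceeds twice the SE of the
difference.

**K-fold cross-validation.** PSIS-LOO reweights posterior draws by
inverse pointwise densities, which assumes the draws represent the
posterior well. For the 80-coefficient all-spline model the Laplace
draws are systematically overdispersed relative to the true posterior
(see above), importance weights degenerate, and PSIS-LOO understates
that model's ELPD by an amount comparable to its real advantage. A
K-fold estimator (`kfold_elpd`, default 10 folds) refits per fold and
scores each held-out observation by `log mean_s exp(loglik)`; the
exponential average is dominated by the best draws, making it robust
to approximate draws. On well-approximated models it agrees with
PSIS-LOO to within a couple of ELPD units (tested); for comparisons
involving the all-spline model it is the estimator of record here.

**QQ RMSE.** Within each sex and five-year age bin, the deciles
(10–90) of observed partner ages are compared with the deciles of
pooled posterior-predictive partner ages (10 replicates per
observation, so predictive cell sizes are proportional to observed
ones); the RMSE over all bin x sex x level errors is reported, in
years. Empirical quantiles interpolate linearly between order
statistics — the quantile-type choice moves the statistic by O(0.01)
years at these sample sizes, so it is fixed and documented. Cells are
unweighted; weighting by cell size would be the natural alternative.
The subset comparison uses bins [20,25) … [45,50); the regression
evaluation uses [15,20) … [60,65).

## Synthetic data

The generator runs the model forwards: respondent ages uniform on
15–64 (integer, as surveys record them), sex Bernoulli(0.5), partner
counts 1 + Poisson(1.2) (mean 2.2 partners per respondent, matching
the cohort studies emulated), `y = log(p/a)` drawn from sinh-arcsinh
truth curves over age and sex, and `p = a exp(y)` rounded to whole
years (optional, on by default). Truth curves are specified on the link
scale so linear truths correspond exactly to design-matrix
coefficients. Heaping moves a report, with probability 0.3 in the
heaped scenarios, to the nearest multiple of five of the partner age
(or of the age difference), ties broken downward — the survey
literature describes the phenomenon, not a generative law, so this is
our modelling choice.

Four truth shapes are bundled: constant higher-order parameters
(`conventional_truth`), linear age and sex effects
(`linear_distributional`), sex-asymmetric non-linear trajectories with
a mid-30s peak in the male scale (`spline_shaped`), and heavy tails
with delta = 0.5 (`heavy_tail`), each with a heaped variant. Location
truths give men partners a few years younger and women a few years
older, with the gap narrowing over age, and scale around 0.1 on the
log-ratio scale — magnitudes in line with published summaries of
sub-Saharan cohort and DHS partnership data.

What the generator does **not** emulate: repeat reporting of the same
partnership across survey rounds, within-respondent correlation of
multiple partners' ages, same-sex partnerships, reporting biases, or
survey weights. Passing tests therefore demonstrate correctness of the
machinery under the stated generative structure, not robustness to
those real-data complications.

## Problem sizes used in the checks

The test suite and the acceptance script scale the experiments to desk
size as the package's own study conditions: parameter recovery fits
the 16-coefficient interaction model to ~5,000 partnerships for 20
seeded replicates (coverage is assessed per coefficient block at the
replicate-count-adjusted rate of 0.85, with overall coverage at least
0.90); model-selection recovery runs at the generator's default size of
10,000 respondents (~22,000 partnerships, the scale of the emulated
surveys); the subset-level comparison exercises all 504 fits at ~800
respondents per dataset. The recovery study generates continuous
partner ages so that the fitted model is exactly the generating model;
with integer rounding (the survey default) coverage degrades by a few
percentage points — a real, documented effect of fitting continuous
densities to year-valued reports.

## Known limitations

* The Laplace default understates posterior spread for the
  80-coefficient all-spline model (see above); treat its interval
  estimates with caution and prefer the HMC engine when feasible.
* No mean parametrisation of the sinh-arcsinh is provided: `mu` is a
  location, correlated with but not equal to the mean.
* No deheaping of heaped reports is implemented; the natural hook is a
  records-to-records filter applied before fitting.
* No hierarchical/random effects, survey weights, or penalised
  smoothness estimation.
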