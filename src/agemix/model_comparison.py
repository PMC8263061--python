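"""Model comparison: ELPD (PSIS-LOO / WAIC / exact refit LOO) and QQ RMSE.

The expected log predictive density (ELPD) estimates a model's
log-density at a new, unobserved observation. It is computed from the
S x N pointwise log-likelihood matrix of a fit; because every matrix
entering a comparison is already Jacobian-adjusted to the common
partner-age scale, models of different outcome transforms are directly
comparable. Two models differ "significantly" when |delta ELPD| exceeds
twice the standard error of the paired difference.

QQ RMSE measures predictive accuracy in years: within each sex and
five-year age bin, the deciles (10..90) of observed partner ages are
compared with the deciles of pooled posterior-predictive partner ages;
the RMSE over all (bin x sex x level) errors is the root mean squared
distance from the line of equality on a QQ plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from arviz.stats import psislw
from scipy.special import logsumexp

__all__ = [
    "ElpdResult",
    "ComparisonResult",
    "elpd",
    "exact_loo",
    "kfold_elpd",
    "compare_models",
    "compare_elpd_results",
    "qq_rmse",
    "DEFAULT_QUANTILE_LEVELS",
]

DEFAULT_QUANTILE_LEVELS = np.arange(0.1, 0.91, 0.1)
PARETO_K_WARN = 0.7


@dataclass
class ElpdResult:
    elpd: float
    se: float
    pointwise: np.ndarray  # per-observation contributions (N,)
    method: str
    pareto_k: np.ndarray | None = None
    p_eff: float | None = None

    @property
    def n_obs(self) -> int:
        return self.pointwise.size


def _check_matrix(pointwise):
    ll = np.asarray(pointwise, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be an (S, N) matrix")
    return ll


def _se(contrib):
    n = contrib.size
    return float(np.sqrt(n * np.var(contrib)))


def elpd(pointwise, method: str = "psis_loo") -> ElpdResult:
    """ELPD from an (S, N) pointwise log-likelihood matrix.

    * ``psis_loo`` — Pareto-smoothed importance-sampling leave-one-out:
      per observation the importance weights 1/p(y_i | theta_s) have
      their upper tail (top 20%) replaced by fitted generalised-Pareto
      quantiles; per-observation Pareto-k diagnostics are attached and a
      warning raised when any k > 0.7.
    * ``waic`` — lppd_i - p_waic_i with p_waic_i the posterior variance
      of the log-density.

    SE = sqrt(N * var(per-observation contributions)).
    """
    ll = _check_matrix(pointwise)
    S, N = ll.shape
    if method in ("psis_loo", "waic") and S < 100:
        warnings.warn(f"only {S} draws; ELPD estimates may be unstable")
    if method == "psis_loo":
        var = np.var(ll, axis=0)
        if np.all(var < 1e-14):
            # point-mass posterior: weights are uniform and LOO is exact
            contrib = ll[0]
            k = np.full(N, -np.inf)
        else:
            lw = xr.DataArray(-ll.T, dims=("obs", "__sample__"))
            smoothed, k = psislw(lw, reff=1.0)
            smoothed = np.asarray(smoothed).T  # back to (S, N)
            k = np.asarray(k)
            contrib = logsumexp(smoothed + ll, axis=0)
        if np.any(np.asarray(k) > PARETO_K_WARN):
            warnings.warn(
                f"{int(np.sum(np.asarray(k) > PARETO_K_WARN))} observations have "
                f"Pareto k > {PARETO_K_WARN}; PSIS-LOO may be unreliable"
            )
        return ElpdResult(float(np.sum(contrib)), _se(contrib), contrib, method, pareto_k=np.asarray(k))
    if method == "waic":
        lppd = logsumexp(ll, axis=0) - np.log(S)
        p_waic = np.var(ll, axis=0, ddof=1) if S > 1 else np.zeros(N)
        contrib = lppd - p_waic
        return ElpdResult(
            float(np.sum(contrib)), _se(contrib), contrib, method, p_eff=float(np.sum(p_waic))
        )
    raise ValueError(f"unknown method {method!r}; use psis_loo or waic")


def exact_loo(records, loglik_fn) -> ElpdResult:
    """Brute-force leave-one-out: refit N times (test scale only).

    ``loglik_fn(train_records, test_records) -> (S, n_test) matrix`` must
    refit on the training rows and score the held-out rows on the common
    age scale. The contribution of observation i is
    log mean_s exp(loglik_i^s) under the fit without i.
    """
    records = pd.DataFrame(records).reset_index(drop=True)
    n = len(records)
    contrib = np.empty(n)
    for i in range(n):
        train = records.drop(index=i)
        test = records.iloc[[i]]
        ll = _check_matrix(loglik_fn(train, test))
        contrib[i] = logsumexp(ll[:, 0]) - np.log(ll.shape[0])
    return ElpdResult(float(np.sum(contrib)), _se(contrib), contrib, "exact_loo")


def kfold_elpd(records, fit_fn, k: int = 10, seed: int = 0) -> ElpdResult:
    """K-fold cross-validated ELPD with posterior-predictive scoring.

    ``fit_fn(train_records)`` must return a fitted model exposing
    ``pointwise_for(test_records)`` (an (S, n) age-scale log-likelihood
    matrix); each held-out observation contributes
    ``log mean_s exp(ll_s)``. Unlike PSIS-LOO, this estimator does not
    reweight draws by inverse densities, so it stays reliable when the
    posterior draws are approximate (for example Laplace draws of
    high-dimensional spline models, where importance weights degenerate).
    """
    records = pd.DataFrame(records).reset_index(drop=True)
    n = len(records)
    if k < 2 or k > n:
        raise ValueError("k must be between 2 and the number of observations")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    contrib = np.empty(n)
    for fold in folds:
        mask = np.ones(n, bool)
        mask[fold] = False
        fit = fit_fn(records[mask])
        ll = _check_matrix(fit.pointwise_for(records.iloc[fold]))
        contrib[fold] = logsumexp(ll, axis=0) - np.log(ll.shape[0])
    return ElpdResult(float(np.sum(contrib)), _se(contrib), contrib, "kfold")


@dataclass
class ComparisonResult:
    """Per-model ELPDs plus pairwise differences with the 2-SE rule."""

    names: list
    elpds: dict  # name -> ElpdResult
    table: pd.DataFrame  # tidy per-model summary
    pairwise: pd.DataFrame  # model_a, model_b, delta, delta_se, significant

    def best(self) -> str:
        return self.table.iloc[0]["model"]


def compare_models(pointwise_by_model: dict, method: str = "psis_loo") -> ComparisonResult:
    """Compare models on a common, Jacobian-adjusted observation set.

    ``pointwise_by_model`` maps model name to its (S, N) matrix; all
    matrices must cover the same N observations in the same order. The
    pairwise difference SE comes from the paired per-observation
    contribution differences; a model is flagged significantly better
    when |delta| / SE(delta) > 2.
    """
    mats = {k: _check_matrix(v) for k, v in pointwise_by_model.items()}
    n_obs = {k: m.shape[1] for k, m in mats.items()}
    if len(set(n_obs.values())) != 1:
        raise ValueError(f"models evaluated on different observation sets: {n_obs}")
    return compare_elpd_results({k: elpd(m, method=method) for k, m in mats.items()})


def compare_elpd_results(results: dict) -> ComparisonResult:
    """Build the comparison tables from per-model ElpdResults whose
    pointwise contributions cover the same observations."""
    names = list(results)
    n_obs = {k: r.n_obs for k, r in results.items()}
    if len(set(n_obs.values())) != 1:
        raise ValueError(f"models evaluated on different observation sets: {n_obs}")
    order = sorted(names, key=lambda k: results[k].elpd, reverse=True)
    best = order[0]
    rows = []
    for k in order:
        r = results[k]
        d = results[best].pointwise - r.pointwise
        delta = float(np.sum(d))
        delta_se = _se(d) if k != best else 0.0
        rows.append(
            {
                "model": k,
                "elpd": r.elpd,
                "se": r.se,
                "delta_vs_best": -delta,
                "delta_se": delta_se,
                "significant": bool(k != best and delta > 2.0 * delta_se and delta_se > 0),
            }
        )
    table = pd.DataFrame(rows)

    pair_rows = []
    for i, ka in enumerate(names):
        for kb in names[i + 1 :]:
            d = results[ka].pointwise - results[kb].pointwise
            delta = float(np.sum(d))
            dse = _se(d)
            pair_rows.append(
                {
                    "model_a": ka,
                    "model_b": kb,
                    "delta_elpd": delta,
                    "delta_se": dse,
                    "significant": bool(dse > 0 and abs(delta) > 2.0 * dse),
                }
            )
    pairwise = pd.DataFrame(pair_rows)
    return ComparisonResult(names=names, elpds=results, table=table, pairwise=pairwise)


def _bin_labels(edges):
    return [f"{int(lo)}-{int(hi) - 1}" for lo, hi in zip(edges[:-1], edges[1:])]


def default_age_bins(lo: int = 20, hi: int = 50):
    """Half-open five-year bins [lo, lo+5), ..., [hi-5, hi)."""
    return np.arange(lo, hi + 1, 5)


def qq_rmse(
    records,
    predictive_samples,
    age_bins=None,
    quantile_levels=DEFAULT_QUANTILE_LEVELS,
) -> float:
    """RMSE (years) between observed and predictive deciles by bin and sex.

    ``predictive_samples`` is an (N, m) array aligned with the records:
    m posterior-predictive partner ages per observation, pooled within
    each (sex, age-bin) cell so predictive cell sizes are proportional
    to observed ones. Empirical quantiles use linear interpolation
    between order statistics. Raises on any empty cell.
    """
    records = pd.DataFrame(records).reset_index(drop=True)
    pred = np.asarray(predictive_samples, dtype=float)
    if pred.ndim == 1:
        pred = pred[:, None]
    if pred.shape[0] != len(records):
        raise ValueError("predictive samples must align with records rows")
    if age_bins is None:
        age_bins = default_age_bins()
    age_bins = np.asarray(age_bins, dtype=float)
    ages = records["respondent_age"].to_numpy(dtype=float)
    sexes = records["respondent_sex"].to_numpy(dtype=int)
    obs = records["partner_age"].to_numpy(dtype=float)

    errors = []
    for sex in sorted(np.unique(sexes)):
        for lo, hi in zip(age_bins[:-1], age_bins[1:]):
            mask = (sexes == sex) & (ages >= lo) & (ages < hi)
            if not np.any(mask):
                raise ValueError(f"empty cell: sex={sex}, age bin [{int(lo)}, {int(hi)})")
            q_obs = np.quantile(obs[mask], quantile_levels)
            q_pred = np.quantile(pred[mask].ravel(), quantile_levels)
            errors.append(q_pred - q_obs)
    errors = np.concatenate(errors)
    return float(np.sqrt(np.mean(errors**2)))
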