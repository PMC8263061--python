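"""End-to-end experiments: subset-level distribution comparison and the
five-model distributional-regression evaluation.

Experiment 1 (``run_distribution_comparison``) splits each labelled
dataset into sex x five-year age bin subsets (20-24 ... 45-49; ages
15-19 are omitted because their small samples make comparison
unreliable) and fits every viable distribution-outcome combination to
each subset independently with intercept-only designs: four outcomes
for the normal, skew normal and sinh-arcsinh families, plus linear age
only for the gamma (with the male reflection) and beta (with unit
scaling) families — 14 combinations per subset. With three datasets
that is 36 subsets and 504 fits. ELPDs are Jacobian-adjusted to the
partner-age scale so outcomes are comparable.

Experiment 2 (``run_regression_evaluation``) fits the five benchmark
design configurations (Conventional through Distributional 4) of the
sinh-arcsinh log-ratio model to a full dataset spanning ages 15-64,
compares ELPD (with 2-SE significance flags) and QQ RMSE, and exports
fitted parameter trajectories over age and sex.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import model_comparison as mc
from . import regression as reg

logger = logging.getLogger("agemix")

__all__ = [
    "SubsetKey",
    "enumerate_subsets",
    "viable_combinations",
    "run_distribution_comparison",
    "run_regression_evaluation",
    "COMPARISON_BINS",
    "REGRESSION_BINS",
]

COMPARISON_BINS = np.arange(20, 51, 5)  # [20,25) ... [45,50)
REGRESSION_BINS = np.arange(15, 66, 5)  # [15,20) ... [60,65)

# outcomes per family in the subset comparison: restricted-domain
# families take linear age only, through their support transforms
_FULL_OUTCOME_FAMILIES = ("normal", "skew_normal", "sinh_arcsinh")
_OUTCOMES = ("linear_age", "age_difference", "log_age", "log_ratio")


def viable_combinations():
    """The 14 (family, outcome, support) combinations fit per subset."""
    combos = [(f, o, "identity") for f in _FULL_OUTCOME_FAMILIES for o in _OUTCOMES]
    combos.append(("gamma", "linear_age", "gamma_male_reflection"))
    combos.append(("beta", "linear_age", "beta_unit_scaling"))
    return combos


def enumerate_subsets(dataset_labels, age_bins=COMPARISON_BINS):
    """All (dataset, sex, bin-start) subset keys."""
    return [
        SubsetKey(label, sex, int(lo))
        for label in dataset_labels
        for sex in (0, 1)
        for lo in np.asarray(age_bins)[:-1]
    ]


class SubsetKey(tuple):
    """(dataset, sex, age-bin start); bins are half-open five-year bins."""

    def __new__(cls, dataset, sex, bin_lo):
        return super().__new__(cls, (dataset, sex, int(bin_lo)))

    dataset = property(lambda self: self[0])
    sex = property(lambda self: self[1])
    bin_lo = property(lambda self: self[2])


def _subset_rows(df, key: SubsetKey):
    return df[
        (df["respondent_sex"] == key.sex)
        & (df["respondent_age"] >= key.bin_lo)
        & (df["respondent_age"] < key.bin_lo + 5)
    ]


def run_distribution_comparison(
    datasets: dict,
    seed: int = 0,
    engine: str = "map",
    draws: int = 400,
    draws_per_obs: int = 10,
    min_subset_size: int = 30,
    outdir=None,
) -> dict:
    """Fit all viable distribution-outcome combinations to every subset.

    Returns ``{"fits": tidy per-fit table, "best_outcomes": share table
    (per-family percent of subsets in which each outcome has the top
    ELPD), "family_summary": per-dataset family averages of ELPD and QQ
    RMSE at each subset's best outcome, "best_family": per-subset
    winner}``. Percentages in ``best_outcomes`` sum to 100 per family.
    """
    subsets = enumerate_subsets(datasets.keys())
    combos = viable_combinations()
    rows = []
    fit_i = 0
    for key in subsets:
        sub = _subset_rows(datasets[key.dataset], key)
        if len(sub) < min_subset_size:
            logger.warning("skipping subset %s: only %d records", key, len(sub))
            continue
        bins = np.array([key.bin_lo, key.bin_lo + 5])
        for family, outcome, support in combos:
            t0 = time.perf_counter()
            spec = reg.intercept_only_spec(family, outcome, support, name=f"{family}:{outcome}")
            fit_seed = (seed * 10_007 + fit_i) % (2**31)
            fit_i += 1
            fr = reg.fit(sub, spec, engine=engine, draws=draws, seed=fit_seed)
            er = mc.elpd(fr.pointwise)
            pred = reg.posterior_predict(
                fr,
                sub["respondent_age"],
                sub["respondent_sex"],
                draws_per_obs=draws_per_obs,
                seed=fit_seed + 1,
            )
            qq = mc.qq_rmse(sub, pred, age_bins=bins)
            rows.append(
                {
                    "dataset": key.dataset,
                    "sex": key.sex,
                    "age_bin": f"{key.bin_lo}-{key.bin_lo + 4}",
                    "family": family,
                    "outcome": outcome,
                    "n": len(sub),
                    "elpd": er.elpd,
                    "elpd_se": er.se,
                    "qq_rmse": qq,
                    "converged": fr.converged,
                }
            )
            logger.info(
                "fit %s %s/%s on %s: elpd=%.1f qq=%.2f (%.2fs)",
                key,
                family,
                outcome,
                f"n={len(sub)}",
                er.elpd,
                qq,
                time.perf_counter() - t0,
            )
    fits = pd.DataFrame(rows)

    # each family's best outcome per subset (by ELPD)
    gb = fits.groupby(["dataset", "sex", "age_bin", "family"], sort=False)
    best = fits.loc[gb["elpd"].idxmax()].reset_index(drop=True)

    shares = (
        best[best["family"].isin(_FULL_OUTCOME_FAMILIES)]
        .groupby(["family", "outcome"])
        .size()
        .unstack(fill_value=0)
    )
    shares = (100.0 * shares.div(shares.sum(axis=1), axis=0)).T

    family_summary = (
        best.groupby(["dataset", "family"])[["elpd", "qq_rmse"]].mean().reset_index()
    )

    per_subset = best.loc[
        best.groupby(["dataset", "sex", "age_bin"], sort=False)["elpd"].idxmax(),
        ["dataset", "sex", "age_bin", "family", "outcome", "elpd"],
    ].reset_index(drop=True)

    out = {
        "fits": fits,
        "best_outcomes": shares,
        "family_summary": family_summary,
        "best_family": per_subset,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fits.to_csv(outdir / "distribution_fits.csv", index=False)
        shares.to_csv(outdir / "best_outcome_shares.csv")
        family_summary.to_csv(outdir / "family_summary.csv", index=False)
        per_subset.to_csv(outdir / "best_family_per_subset.csv", index=False)
    return out


REGRESSION_MODEL_ORDER = list(reg.TABLE2_MODELS)


def run_regression_evaluation(
    records,
    seed: int = 0,
    engine: str = "map",
    draws: int = 400,
    draws_per_obs: int = 10,
    models=None,
    elpd_method: str = "psis_loo",
    kfold_k: int = 10,
    outdir=None,
    plots: bool = False,
) -> dict:
    """Fit the five benchmark specs and compare ELPD / QQ RMSE.

    ``elpd_method`` is ``psis_loo`` (default; cheap, with Pareto-k
    diagnostics) or ``kfold`` (K-fold cross-validation with refits per
    fold; robust when approximate draws of the high-dimensional spline
    models make importance weights unreliable).

    Returns ``{"table": 5-row summary (model, elpd, se, delta_vs_best,
    delta_se, significant, qq_rmse, converged), "comparison":
    ComparisonResult, "trajectories": fitted parameter curves over age
    and sex, "fits": name -> FitResult}``.
    """
    records = pd.DataFrame(records)
    if records["respondent_sex"].nunique() < 2:
        raise ValueError("regression evaluation needs records from both sexes")
    names = list(models) if models is not None else list(REGRESSION_MODEL_ORDER)
    fits, qq, converged = {}, {}, {}
    for j, name in enumerate(names):
        t0 = time.perf_counter()
        spec = reg.make_table2_spec(name)
        fit_seed = (seed * 10_007 + j) % (2**31)
        try:
            fr = reg.fit(records, spec, engine=engine, draws=draws, seed=fit_seed)
        except Exception as exc:  # keep the run going, report the failure
            logger.error("fit of %s failed: %s", name, exc)
            converged[name] = False
            continue
        fits[name] = fr
        converged[name] = fr.converged
        pred = reg.posterior_predict(
            fr,
            records["respondent_age"],
            records["respondent_sex"],
            draws_per_obs=draws_per_obs,
            seed=fit_seed + 1,
        )
        qq[name] = mc.qq_rmse(records, pred, age_bins=REGRESSION_BINS)
        logger.info("fit %s in %.1fs (qq=%.2f)", name, time.perf_counter() - t0, qq[name])

    if elpd_method == "kfold":
        results = {}
        for j, name in enumerate(fits):
            spec = reg.make_table2_spec(name)
            fit_seed = (seed * 10_007 + 101 + j) % (2**31)
            results[name] = mc.kfold_elpd(
                records,
                lambda train, _s=spec, _fs=fit_seed: reg.fit(
                    train, _s, engine=engine, draws=draws, seed=_fs
                ),
                k=kfold_k,
                seed=seed,
            )
        comparison = mc.compare_elpd_results(results)
    else:
        comparison = mc.compare_models(
            {k: v.pointwise for k, v in fits.items()}, method=elpd_method
        )
    table = comparison.table.copy()
    table["qq_rmse"] = table["model"].map(qq)
    table["converged"] = table["model"].map(converged)
    # present in complexity order
    table = (
        table.set_index("model").loc[[n for n in names if n in fits]].reset_index()
    )

    traj_rows = []
    ages = np.arange(15, 65)
    for name, fr in fits.items():
        for sex in (0, 1):
            nat = fr.linear_predictors(ages, np.full(ages.shape, sex))
            for pname in ("mu", "sigma", "sigma_star", "epsilon", "delta"):
                if pname not in nat:
                    continue
                med = np.median(nat[pname], axis=0)
                lo_b, hi_b = np.percentile(nat[pname], [2.5, 97.5], axis=0)
                traj_rows.extend(
                    {
                        "model": name,
                        "sex": sex,
                        "age": int(ag),
                        "parameter": pname,
                        "median": float(m),
                        "lower95": float(l),
                        "upper95": float(h),
                    }
                    for ag, m, l, h in zip(ages, med, lo_b, hi_b)
                )
    trajectories = pd.DataFrame(traj_rows)

    out = {"table": table, "comparison": comparison, "trajectories": trajectories, "fits": fits}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "regression_table.csv", index=False)
        comparison.pairwise.to_csv(outdir / "regression_pairwise.csv", index=False)
        trajectories.to_csv(outdir / "parameter_trajectories.csv", index=False)
        best = table.sort_values("elpd", ascending=False).iloc[0]["model"]
        if best in fits:
            overlays = predictive_overlay_table(fits[best], records, seed=seed)
            overlays.to_csv(outdir / "predictive_overlays.csv", index=False)
            if plots:
                _plot_overlays(overlays, best, outdir / "predictive_overlays.png")
                _plot_trajectories(
                    trajectories[trajectories["model"] == best],
                    best,
                    outdir / "parameter_trajectories.png",
                )
    return out


def predictive_overlay_table(fit, records, ages=(20, 30, 40), seed=0, n_rep=200):
    """Observed vs posterior-predictive partner-age distributions.

    For each requested respondent age and each sex, tabulates the
    observed partner-age histogram (respondents within +/-1 year) next
    to pooled posterior-predictive samples, in tidy long format.
    """
    records = pd.DataFrame(records)
    rows = []
    for sex in (0, 1):
        for age in ages:
            obs = records[
                (records["respondent_sex"] == sex)
                & (records["respondent_age"].sub(age).abs() <= 1)
            ]["partner_age"]
            pred = reg.posterior_predict(
                fit, np.full(n_rep, float(age)), np.full(n_rep, sex), draws_per_obs=10, seed=seed
            ).ravel()
            rows.extend(
                {"respondent_age": age, "sex": sex, "kind": "observed", "partner_age": float(v)}
                for v in obs
            )
            rows.extend(
                {"respondent_age": age, "sex": sex, "kind": "predicted", "partner_age": float(v)}
                for v in pred
            )
    return pd.DataFrame(rows)


def _plot_overlays(overlays, model_name, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ages = sorted(overlays["respondent_age"].unique())
    fig, axes = plt.subplots(2, len(ages), figsize=(4 * len(ages), 6), squeeze=False)
    for i, sex in enumerate((0, 1)):
        for j, age in enumerate(ages):
            ax = axes[i][j]
            cell = overlays[(overlays["sex"] == sex) & (overlays["respondent_age"] == age)]
            bins = np.arange(10, 80, 2)
            ax.hist(
                cell[cell["kind"] == "observed"]["partner_age"],
                bins=bins, density=True, alpha=0.5, color="grey", label="observed",
            )
            ax.hist(
                cell[cell["kind"] == "predicted"]["partner_age"],
                bins=bins, density=True, histtype="step", color="C1", label="predicted",
            )
            ax.set_title(f"{'women' if sex else 'men'} aged {age}")
            if i == 1:
                ax.set_xlabel("partner age (years)")
    axes[0][0].legend()
    fig.suptitle(f"Posterior-predictive partner ages ({model_name})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_trajectories(traj, model_name, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = ["mu", "sigma", "epsilon", "delta"]
    fig, axes = plt.subplots(1, len(params), figsize=(4 * len(params), 3.2))
    for ax, pname in zip(axes, params):
        for sex, color in ((0, "C0"), (1, "C3")):
            cell = traj[(traj["parameter"] == pname) & (traj["sex"] == sex)]
            ax.plot(cell["age"], cell["median"], color=color, label="women" if sex else "men")
            ax.fill_between(cell["age"], cell["lower95"], cell["upper95"], color=color, alpha=0.2)
        ax.set_title(pname)
        ax.set_xlabel("respondent age")
    axes[0].legend()
    fig.suptitle(f"Fitted distributional parameters ({model_name})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
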