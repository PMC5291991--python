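"""4-fold train/validation ROC comparison of the four models.

The cohort is partitioned at the individual level into four disjoint 25%
validation folds; for each fold, every model is fitted on the complementary
75% and scored on both partitions by the area under the ROC curve (rank-sum
concordance with midranks for ties).  Hierarchical models score with
conditional probabilities (training-fit community effects; communities appear
in both partitions because the split is by individual); joint models score
with marginal probabilities.
"""

from __future__ import annotations

import traceback
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import bayes, dgam, dglm, glmm
from .cohort import COMMUNITY_COL, CohortTable
from .glm import GLMSpec

__all__ = [
    "MODEL_NAMES",
    "SplitPlan",
    "ComparisonReport",
    "make_splits",
    "auc",
    "run_comparison",
    "default_model_configs",
]

MODEL_NAMES = ("hier-freq", "hier-bayes", "joint-glm", "joint-gam")


@dataclass
class SplitPlan:
    """Four mutually exclusive, exhaustive validation index sets."""

    n: int
    folds: list  # list of 4 index arrays
    seed: int

    def validate(self) -> None:
        allidx = np.concatenate(self.folds)
        if len(allidx) != self.n or len(np.unique(allidx)) != self.n:
            raise ValueError("folds do not partition the rows")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes {sizes} differ by more than 1")


@dataclass
class ComparisonReport:
    """Per-model, per-replicate training/validation AUC table plus the
    side-by-side full-data coefficient tables."""

    auc_table: pd.DataFrame  # columns: model, replicate, partition, auc, failed
    coefficients: Optional[pd.DataFrame]
    seed: int
    meta: dict = field(default_factory=dict)

    def pivot(self) -> pd.DataFrame:
        return self.auc_table.pivot_table(
            index="model", columns=["replicate", "partition"], values="auc"
        )


def make_splits(n: int, seed: int) -> SplitPlan:
    """Uniform random partition of {0..n-1} into 4 folds (sizes within 1)."""
    if n < 8:
        raise ValueError("need at least 8 rows for a 4-fold split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [np.sort(f) for f in np.array_split(perm, 4)]
    plan = SplitPlan(n=n, folds=folds, seed=seed)
    plan.validate()
    return plan


def auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve = Mann-Whitney concordance, ties counted 1/2.

    Computed by the rank-sum formula with midranks; O(n log n).
    """
    y = np.asarray(y)
    scores = np.asarray(scores, float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0:
        raise ValueError("AUC undefined: no positive (y=1) observations")
    if n0 == 0:
        raise ValueError("AUC undefined: no negative (y=0) observations")
    r = rankdata(scores, method="average")
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def default_model_configs(cohort: CohortTable, fast: bool = False) -> dict:
    """Reasonable per-model settings derived from the cohort's columns.

    All covariates enter every mean model; the dispersion submodels carry the
    arrest indicator; smooths go on covariates with >= 10 distinct values.
    ``fast=True`` shortens the MCMC and drops quadrature order, for fold-level
    refits.
    """
    covs = cohort.covariate_names
    slope = "arrested" if "arrested" in covs else None
    continuous = [c for c in covs if cohort.data[c].nunique() >= 10]
    disp_covs = ["arrested"] if "arrested" in covs else []
    return {
        "hier-freq": {
            "fixed": covs,
            "re": glmm.RandomEffectsSpec(group=COMMUNITY_COL, slope=slope),
            "quad_order": 1 if fast else 7,
        },
        "hier-bayes": {
            "fixed": covs,
            "re": glmm.RandomEffectsSpec(group=COMMUNITY_COL, slope=slope),
            "priors": bayes.PriorSpec(),
            "iters": 3000 if fast else 20000,
            "burn_in": 1000 if fast else 5000,
            "thin": 2 if fast else 5,
            "chains": 2,
        },
        "joint-glm": {
            "mean_covariates": covs,
            "dispersion": dglm.DispersionSpec(covariates=disp_covs),
        },
        "joint-gam": {
            "smooths": [dgam.SmoothSpec(name=c) for c in continuous],
            "parametric": [c for c in covs if c not in continuous],
            "dispersion": dglm.DispersionSpec(covariates=disp_covs),
        },
    }


def _fit_and_score(model, cfg, train, test, seed):
    """Fit one model on the training subcohort; return scores for both."""
    if model == "hier-freq":
        fit = glmm.fit_glmm(
            train,
            fixed=cfg["fixed"],
            re=cfg["re"],
            quad_order=cfg.get("quad_order", 7),
            compute_se=False,
        )
        return (
            glmm.conditional_predict(fit, train.data),
            glmm.conditional_predict(fit, test.data),
            fit,
        )
    if model == "hier-bayes":
        sample = bayes.run_mcmc(
            train,
            fixed=cfg["fixed"],
            re=cfg["re"],
            priors=cfg.get("priors"),
            iters=cfg.get("iters", 20000),
            burn_in=cfg.get("burn_in", 5000),
            chains=cfg.get("chains", 2),
            thin=cfg.get("thin", 5),
            seed=seed,
        )
        method = cfg.get("predict", "plugin")
        return (
            bayes.predict(sample, train.data, method=method),
            bayes.predict(sample, test.data, method=method),
            sample,
        )
    if model == "joint-glm":
        fit = dglm.fit_double_glm(
            train,
            mean_spec=GLMSpec(
                family="binomial", link="logit", response="y",
                covariates=cfg["mean_covariates"],
            ),
            disp_spec=cfg["dispersion"],
        )
        return fit.predict(train.data), fit.predict(test.data), fit
    if model == "joint-gam":
        fit = dgam.fit_double_gam(
            train,
            smooths=cfg["smooths"],
            parametric=cfg["parametric"],
            disp_spec=cfg["dispersion"],
        )
        return fit.predict(train.data), fit.predict(test.data), fit
    raise ValueError(f"unknown model {model!r}; valid names: {list(MODEL_NAMES)}")


def _coefficient_table(full_fits: dict) -> Optional[pd.DataFrame]:
    """Side-by-side full-data coefficient estimates (Table-2-style layout)."""
    cols = {}
    for model, fit in full_fits.items():
        if fit is None:
            continue
        if model == "hier-freq":
            s = fit.params.copy()
            s["var[Intercept]"] = fit.delta0_sq
            if fit.delta1_sq is not None:
                s["var[Arrested]"] = fit.delta1_sq
                s["cov[int & Slope]"] = fit.sigma01
            cols[model] = s
        elif model == "hier-bayes":
            s = fit.posterior_mean_beta().copy()
            flat_cov = fit.cov.reshape(-1, fit.cov.shape[-1]).mean(axis=0)
            for i, n in enumerate(bayes.VC_NAMES[: len(flat_cov)]):
                s[n] = flat_cov[i]
            cols[model] = s
        elif model == "joint-glm":
            cols[model] = fit.mean_fit.params
            cols[model + " (dispersion)"] = fit.disp_fit.params
        elif model == "joint-gam":
            s = pd.Series(
                fit.coef[: 1 + len(fit.parametric)],
                index=["Intercept"] + list(fit.parametric),
            )
            cols[model] = s
            cols[model + " (dispersion)"] = fit.disp_fit.params
    if not cols:
        return None
    return pd.DataFrame(cols)


def run_comparison(
    cohort: CohortTable,
    configs: Optional[dict] = None,
    seed: int = 0,
    models=MODEL_NAMES,
    fit_full: bool = True,
    independent_redraws: bool = False,
) -> ComparisonReport:
    """Run the 4-fold train/validation AUC comparison.

    A failing model leaves its cells marked failed and the run continues.
    ``independent_redraws`` draws four independent 75/25 splits instead of a
    disjoint 4-fold partition.
    """
    unknown = [m for m in models if m not in MODEL_NAMES]
    if unknown:
        raise ValueError(f"unknown models {unknown}; valid names: {list(MODEL_NAMES)}")
    if configs is None:
        configs = default_model_configs(cohort)
    n = cohort.n
    rng_seed = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_seed.spawn(8)]
    if independent_redraws:
        rng = np.random.default_rng(sub_seeds[0])
        folds = [
            np.sort(rng.permutation(n)[: n // 4]) for _ in range(4)
        ]
    else:
        folds = make_splits(n, sub_seeds[0]).folds

    records = []
    y = cohort.data["y"].to_numpy()
    for rep, val_idx in enumerate(folds, start=1):
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        train = CohortTable(cohort.data.iloc[train_idx].reset_index(drop=True))
        test = CohortTable(cohort.data.iloc[val_idx].reset_index(drop=True))
        for mi, model in enumerate(models):
            try:
                s_train, s_test, _ = _fit_and_score(
                    model, configs[model], train, test, seed=sub_seeds[1 + mi]
                )
                records.append(
                    dict(model=model, replicate=rep, partition="training",
                         auc=auc(y[train_idx], s_train), failed=False)
                )
                records.append(
                    dict(model=model, replicate=rep, partition="validation",
                         auc=auc(y[val_idx], s_test), failed=False)
                )
            except Exception:
                warnings.warn(
                    f"model {model} failed on replicate {rep}:\n"
                    + traceback.format_exc(limit=1),
                    RuntimeWarning,
                )
                for part in ("training", "validation"):
                    records.append(
                        dict(model=model, replicate=rep, partition=part,
                             auc=np.nan, failed=True)
                    )

    coef = None
    if fit_full:
        full_fits = {}
        for mi, model in enumerate(models):
            try:
                _, _, fit = _fit_and_score(
                    model, configs[model], cohort, cohort, seed=sub_seeds[5]
                )
                full_fits[model] = fit
            except Exception:
                full_fits[model] = None
        coef = _coefficient_table(full_fits)

    return ComparisonReport(
        auc_table=pd.DataFrame(records),
        coefficients=coef,
        seed=seed,
        meta={"n": n, "models": list(models), "independent_redraws": independent_redraws},
    )
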