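"""GLMM: quadrature accuracy, null-variance recovery, ICC identities,
conditional prediction, ML optimality."""

import math

import numpy as np
import pandas as pd
import pytest

from corrbin import cohort, glmm
from corrbin.cohort import CohortTable, GeneratorParams
from corrbin.glmm import (
    RandomEffectsSpec,
    conditional_predict,
    fit_glmm,
    icc_unconditional,
    latent_threshold_icc,
    profile_loglik,
)


def test_laplace_and_agh7_agree_to_three_decimals():
    # moderately large communities, where the Laplace approximation is sharp
    p = cohort.default_addhealth_params(seed=4)
    p.n_communities = 15
    p.total_n = 1500
    p.covariates = p.covariates[:5]
    keep = {"intercept"} | {c.name for c in p.covariates}
    p.beta = {k: v for k, v in p.beta.items() if k in keep}
    tab = cohort.generate(p)
    f1 = fit_glmm(tab, tab.covariate_names, quad_order=1, compute_se=False)
    f7 = fit_glmm(tab, tab.covariate_names, quad_order=7, compute_se=False)
    np.testing.assert_allclose(f1.params.to_numpy(), f7.params.to_numpy(), atol=1e-3)
    assert abs(f1.delta0_sq - f7.delta0_sq) < 1e-2
    assert abs(f1.delta1_sq - f7.delta1_sq) < 1e-2


def test_null_variance_recovery():
    # no clustering at all: fixed effects recovered, variances near zero
    p = cohort.default_addhealth_params(seed=77)
    p.delta0_sq = p.delta1_sq = p.sigma01 = 0.0
    p.n_communities = 40
    p.total_n = 8000
    p.covariates = p.covariates[:8]
    keep = {"intercept"} | {c.name for c in p.covariates}
    p.beta = {k: v for k, v in p.beta.items() if k in keep}
    tab = cohort.generate(p)
    fit = fit_glmm(tab, tab.covariate_names, quad_order=1)
    assert fit.delta0_sq < 0.02
    assert fit.delta1_sq < 0.02
    assert fit.boundary
    for name in tab.covariate_names:
        se = fit.bse[name]
        if np.isfinite(se) and se > 0:
            assert abs(fit.params[name] - p.beta[name]) < 4 * se + 0.02, name


def test_single_community_rejected():
    data = pd.DataFrame(
        {"y": [0, 1] * 10, "community": [0] * 20, "arrested": [0, 1] * 10}
    )
    with pytest.raises(ValueError, match="< 2 levels"):
        fit_glmm(CohortTable(data=data), ["arrested"])


def test_constant_slope_covariate_rejected():
    data = pd.DataFrame(
        {
            "y": [0, 1] * 20,
            "community": [0, 1] * 20,
            "arrested": [1.0] * 40,
        }
    )
    with pytest.raises(ValueError, match="does not vary"):
        fit_glmm(CohortTable(data=data), ["arrested"])


@pytest.mark.parametrize(
    "d0sq,expected",
    [(0.0, 0.0), (math.pi**2 / 3.0, 0.5)],
)
def test_latent_threshold_icc_identities(d0sq, expected):
    assert latent_threshold_icc(d0sq) == pytest.approx(expected)


def test_icc_unconditional_recovers_generating_variance():
    params = GeneratorParams(
        beta={"intercept": 0.0},
        covariates=[],
        n_communities=132,
        total_n=4484,
        delta0_sq=0.5624,
        seed=31,
    )
    res = icc_unconditional(cohort.generate(params))
    assert res.warrants_correlated_model
    assert abs(res.icc - 0.146) < 0.05  # single replicate: generous MC band


def test_conditional_predict_monotone_and_unseen_flagged(tiny_cohort):
    fit = fit_glmm(tiny_cohort, tiny_cohort.covariate_names, quad_order=1, compute_se=False)
    base = tiny_cohort.data.iloc[[0]].copy()
    name = "income"  # negative coefficient in the generator
    lo, hi = base.copy(), base.copy()
    lo[name], hi[name] = 0.0, 10.0
    p_lo = conditional_predict(fit, lo)[0]
    p_hi = conditional_predict(fit, hi)[0]
    if fit.params[name] < 0:
        assert p_hi < p_lo
    else:
        assert p_hi > p_lo

    unseen = base.copy()
    unseen["community"] = 99999
    p, flags = conditional_predict(fit, unseen, return_flags=True)
    assert flags[0]
    # gamma = 0 for unseen: equals the pure fixed-effect prediction
    X = np.concatenate([[1.0], unseen[fit.fixed_names].to_numpy(float)[0]])
    eta = X @ fit.params.to_numpy()
    assert p[0] == pytest.approx(1 / (1 + np.exp(-eta)), abs=1e-12)


def test_estimate_attains_higher_likelihood_than_truth():
    p = cohort.default_addhealth_params(seed=15)
    p.n_communities = 30
    p.total_n = 900
    p.covariates = p.covariates[:5]
    keep = {"intercept"} | {c.name for c in p.covariates}
    p.beta = {k: v for k, v in p.beta.items() if k in keep}
    tab = cohort.generate(p)
    fit = fit_glmm(tab, tab.covariate_names, quad_order=7, compute_se=False)
    beta_true = np.array(
        [p.beta["intercept"]] + [p.beta[c] for c in tab.covariate_names]
    )
    ll_true = profile_loglik(
        tab,
        tab.covariate_names,
        RandomEffectsSpec(),
        beta_true,
        p.random_effect_cov(),
        quad_order=7,
    )
    assert fit.loglik >= ll_true - 1e-3
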