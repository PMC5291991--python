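"""IRLS engine: closed-form oracles, reference agreement, deviance
machinery, Hosmer-Lemeshow behaviour."""

import numpy as np
import pandas as pd
import pytest

from corrbin import glm
from corrbin.glm import (
    GLMSpec,
    PerfectSeparationError,
    RankDeficientError,
    hosmer_lemeshow,
    irls_fit,
    unit_deviance,
)


def _table_2x2():
    # counts (y=1,x=1)=30, (y=0,x=1)=20, (y=1,x=0)=10, (y=0,x=0)=40
    y = np.r_[np.ones(30), np.zeros(20), np.ones(10), np.zeros(40)]
    x = np.r_[np.ones(50), np.zeros(50)]
    return pd.DataFrame({"y": y, "x": x})


def test_logistic_slope_equals_log_odds_ratio():
    fit = irls_fit(_table_2x2(), GLMSpec(covariates=["x"]))
    assert fit.converged
    assert fit.params["x"] == pytest.approx(np.log(6.0), abs=1e-6)


def test_intercept_only_logistic_half_prevalence():
    df = pd.DataFrame({"y": [0, 1] * 25})
    fit = irls_fit(df, GLMSpec(covariates=[]))
    assert fit.params["Intercept"] == pytest.approx(0.0, abs=1e-8)


def test_gamma_log_intercept_is_log_mean(rng):
    d = rng.gamma(2.0, 1.5, size=400)
    fit = irls_fit(
        pd.DataFrame({"d": d}),
        GLMSpec(family="gamma", link="log", response="d", covariates=[]),
    )
    assert fit.params["Intercept"] == pytest.approx(np.log(d.mean()), abs=1e-8)


def test_agrees_with_statsmodels_logistic(rng):
    import statsmodels.api as sm

    n = 600
    X = rng.standard_normal((n, 3))
    eta = 0.3 + X @ np.array([0.8, -0.5, 0.2])
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["y"] = y
    ours = irls_fit(df, GLMSpec(covariates=["a", "b", "c"]))
    ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(ours.params.to_numpy(), ref.params, atol=1e-6)
    np.testing.assert_allclose(ours.bse.to_numpy(), ref.bse, atol=1e-5)


def test_weighted_logistic_agrees_with_statsmodels(rng):
    import statsmodels.api as sm

    n = 400
    x = rng.standard_normal(n)
    y = (rng.random(n) < 0.4).astype(float)
    w = rng.uniform(0.2, 3.0, n)
    df = pd.DataFrame({"y": y, "x": x})
    ours = irls_fit(df, GLMSpec(covariates=["x"], prior_weights=w))
    ref = sm.GLM(
        y, sm.add_constant(x), family=sm.families.Binomial(), freq_weights=w
    ).fit()
    np.testing.assert_allclose(ours.params.to_numpy(), ref.params, atol=1e-6)


def test_total_deviance_is_sum_of_unit_deviances():
    fit = irls_fit(_table_2x2(), GLMSpec(covariates=["x"]))
    assert fit.deviance == pytest.approx(fit.unit_deviances.sum(), rel=1e-12)
    assert (fit.unit_deviances >= 0).all()


@pytest.mark.parametrize(
    "y,p,expected",
    [
        (1.0, 1.0 - 1e-12, 0.0),
        (1.0, 0.5, 2 * np.log(2)),
        (0.0, 0.5, 2 * np.log(2)),
    ],
)
def test_unit_deviance_values(y, p, expected):
    assert unit_deviance(np.array([y]), np.array([p]))[0] == pytest.approx(
        expected, abs=1e-9
    )


def test_unit_deviance_clips_boundary_with_warning():
    with pytest.warns(RuntimeWarning, match="clipped"):
        d = unit_deviance(np.array([1.0]), np.array([0.0]))
    assert np.isfinite(d).all()


def test_perfect_separation_raises():
    df = pd.DataFrame({"y": [0] * 20 + [1] * 20, "x": [0.0] * 20 + [1.0] * 20})
    with pytest.raises(PerfectSeparationError):
        irls_fit(df, GLMSpec(covariates=["x"]))


def test_rank_deficiency_names_columns(rng):
    x = rng.standard_normal(50)
    df = pd.DataFrame({"y": (rng.random(50) < 0.5).astype(float), "x": x, "x2": 2 * x})
    with pytest.raises(RankDeficientError, match="x2"):
        irls_fit(df, GLMSpec(covariates=["x", "x2"]))


def test_inadmissible_link_rejected():
    with pytest.raises(ValueError, match="not admissible"):
        GLMSpec(family="binomial", link="log").validate()


def test_hosmer_lemeshow_perfect_calibration_zero():
    # within each decile p equals the observed frequency exactly
    y = np.array([0, 1] * 50, float)
    p = np.full(100, 0.5)
    x2, pval = hosmer_lemeshow(y, p)
    assert x2 == pytest.approx(0.0, abs=1e-10)
    assert pval == pytest.approx(1.0)


def test_hosmer_lemeshow_gross_miscalibration():
    y = np.ones(200)
    p = np.full(200, 0.5)
    x2, pval = hosmer_lemeshow(y, p)
    assert x2 > 50
    assert pval < 1e-3


def test_hosmer_lemeshow_level_under_well_specified_model():
    """Rejection rate at alpha=0.05 stays within the binomial band over 200
    simulated well-specified logistic datasets."""
    rng = np.random.default_rng(2024)
    rejections = 0
    reps = 200
    for _ in range(reps):
        n = 1000
        x = rng.standard_normal(n)
        eta = -0.2 + 0.8 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = irls_fit(pd.DataFrame({"y": y, "x": x}), GLMSpec(covariates=["x"]))
        _, pval = hosmer_lemeshow(y, fit.mu)
        rejections += pval < 0.05
    # Bin(200, 0.05): central 99.5% range approximately [2, 19]
    assert 2 <= rejections <= 19
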