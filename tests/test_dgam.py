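"""Double GAM: GCV selection, penalty limits, collapse to the double GLM,
affine invariance, linear/quadratic truth behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from corrbin import dgam, dglm, glm
from corrbin.cohort import CohortTable
from corrbin.dgam import SmoothSpec, fit_double_gam, gcv_score
from corrbin.dglm import DispersionSpec
from corrbin.glm import GLMSpec


def _smooth_cohort(n=800, effect="linear", seed=0, slope=0.6, quad=0.8):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-2.0, 2.0, n)
    arrested = (rng.random(n) < 0.5).astype(float)
    if effect == "linear":
        f = slope * x
    else:
        f = quad * (x**2 - 2.0)
    eta = 0.2 + 0.4 * arrested + f
    y = (rng.random(n) < expit(eta)).astype(int)
    data = pd.DataFrame(
        {"y": y, "community": rng.integers(0, 10, n), "x": x, "arrested": arrested}
    )
    return CohortTable(data=data)


def _rel_l2_from_line(fit, name="x"):
    tab = fit.smooth_table(name)
    xg, f = tab[name].to_numpy(), tab["fit"].to_numpy()
    A = np.column_stack([np.ones_like(xg), xg])
    coef, *_ = np.linalg.lstsq(A, f, rcond=None)
    line = A @ coef
    denom = np.sqrt(np.mean((line - line.mean()) ** 2))
    return np.sqrt(np.mean((f - line) ** 2)) / denom


def test_linear_truth_yields_nearly_linear_smooth():
    tab = _smooth_cohort(n=4000, effect="linear", seed=5)
    fit = fit_double_gam(tab, [SmoothSpec("x")], ["arrested"],
                         DispersionSpec(covariates=["arrested"]))
    assert _rel_l2_from_line(fit) < 0.05


def test_quadratic_truth_flags_nonlinearity():
    tab = _smooth_cohort(n=1000, effect="quadratic", seed=6)
    fit = fit_double_gam(tab, [SmoothSpec("x")], ["arrested"],
                         DispersionSpec(covariates=["arrested"]))
    assert fit.nonlinearity["p_value"] < 0.05


def test_gcv_selection_matches_grid_refit_oracle():
    tab = _smooth_cohort(n=400, effect="quadratic", seed=9)
    grid = np.logspace(-2, 6, 9)
    fit = fit_double_gam(
        tab, [SmoothSpec("x", penalty_grid=grid)], ["arrested"], DispersionSpec(covariates=[])
    )
    # brute force: force each grid penalty via a single-point grid
    scores = []
    for lam in grid:
        f = fit_double_gam(
            tab,
            [SmoothSpec("x", penalty_grid=np.array([lam]))],
            ["arrested"],
            DispersionSpec(covariates=[]),
        )
        scores.append(f.gcv)
    assert fit.lambdas[0] == pytest.approx(grid[int(np.argmin(scores))])
    assert fit.gcv <= min(scores) + 1e-8


def test_infinite_penalty_reduces_to_linear_fit():
    tab = _smooth_cohort(n=600, effect="linear", seed=2)
    fit = fit_double_gam(
        tab,
        [SmoothSpec("x", penalty_grid=np.array([1e12]))],
        ["arrested"],
        DispersionSpec(covariates=[]),
    )
    # second-difference null space within the sum-to-zero constraint is the
    # linear function: one effective df remains
    assert fit.edf_per_smooth["x"] == pytest.approx(1.0, abs=0.05)
    lin = glm.irls_fit(tab.data, GLMSpec(covariates=["arrested", "x"]))
    assert fit.deviance == pytest.approx(lin.deviance, rel=1e-3)


def test_zero_penalty_uses_full_basis():
    tab = _smooth_cohort(n=300, effect="quadratic", seed=3)
    spec = SmoothSpec("x", basis_dim=8, penalty_grid=np.array([0.0]))
    fit = fit_double_gam(tab, [spec], ["arrested"], DispersionSpec(covariates=[]))
    # 8 basis functions minus the sum-to-zero constraint
    assert fit.edf_per_smooth["x"] == pytest.approx(7.0, abs=0.2)


def test_gcv_score_definition():
    assert gcv_score(100.0, 50, 5.0) == pytest.approx(50 * 100.0 / 45.0**2)
    assert gcv_score(100.0, 50, 50.0) == np.inf


def test_linear_basis_collapses_to_double_glm(small_cohort):
    smooths = [SmoothSpec(name, df=1) for name in ("tv_time", "income")]
    parametric = [c for c in small_cohort.covariate_names if c not in ("tv_time", "income")]
    gam = fit_double_gam(small_cohort, smooths, parametric, DispersionSpec(covariates=[]))
    joint = dglm.fit_double_glm(
        small_cohort,
        GLMSpec(covariates=parametric + ["tv_time", "income"]),
        DispersionSpec(covariates=[]),
    )
    np.testing.assert_allclose(gam.coef, joint.mean_fit.params.to_numpy(), atol=1e-4)


def test_predictions_invariant_to_affine_rescaling():
    tab = _smooth_cohort(n=700, effect="quadratic", seed=13)
    fit1 = fit_double_gam(tab, [SmoothSpec("x")], ["arrested"], DispersionSpec(covariates=[]))
    tab2 = CohortTable(data=tab.data.copy())
    tab2.data["x"] = 3.0 * tab2.data["x"] + 10.0
    fit2 = fit_double_gam(tab2, [SmoothSpec("x")], ["arrested"], DispersionSpec(covariates=[]))
    np.testing.assert_allclose(
        fit1.predict(tab.data), fit2.predict(tab2.data), atol=1e-6
    )


def test_smooth_on_binary_column_rejected(small_cohort):
    with pytest.raises(ValueError, match="distinct"):
        fit_double_gam(
            small_cohort, [SmoothSpec("arrested")], [], DispersionSpec(covariates=[])
        )
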