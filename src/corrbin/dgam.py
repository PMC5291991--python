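"""Double GAM: additive mean submodel with penalized B-spline smooths and a
normal/identity dispersion submodel on the log unit deviances.

The mean submodel is

    logit(p_i) = beta_0 + (parametric terms) + sum_s f_s(X_is),

each f_s a cubic B-spline smooth with knots at quantiles, an integrated
squared-second-derivative (curvature) penalty, and a sum-to-zero constraint
for identifiability.  The smoothing penalty is chosen by generalized cross
validation, GCV = n * Deviance / (n - tr(H))^2, over a logarithmic grid.
The dispersion submodel regresses log(d_i) on its covariates with gaussian
errors and identity link, and its fitted dispersions re-weight the mean
submodel exactly as in the double GLM.

Binary covariates must enter parametrically; a smooth needs >= 10 distinct
covariate values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from scipy.special import expit

from .cohort import CohortTable
from .dglm import DispersionSpec
from .glm import GLMFit, GLMSpec, irls_fit, unit_deviance

__all__ = ["SmoothSpec", "AdditiveFit", "fit_double_gam", "gcv_score"]

DEFAULT_PENALTY_GRID = np.logspace(-3.0, 9.0, 25)


@dataclass
class SmoothSpec:
    """One B-spline smooth: covariate name, target degrees of freedom and a
    penalty grid for GCV.  ``df=1`` degenerates to a plain linear term (used
    by the collapse-to-double-GLM invariant)."""

    name: str
    df: int = 3
    basis_dim: int = 10
    degree: int = 3
    penalty_grid: np.ndarray = field(default_factory=lambda: DEFAULT_PENALTY_GRID.copy())


class _SmoothBasis:
    """Constrained B-spline basis for one covariate.

    Knots sit at quantiles of the training values; the basis is reparametrized
    onto the null space of the sum-to-zero constraint so it carries no
    intercept, and the curvature penalty is mapped along.
    """

    def __init__(self, x: np.ndarray, spec: SmoothSpec):
        x = np.asarray(x, float)
        if np.unique(x).size < 10:
            raise ValueError(
                f"smooth requested on {spec.name!r} with < 10 distinct values; "
                "binary/discrete covariates must enter parametrically"
            )
        self.spec = spec
        self.lo, self.hi = float(x.min()), float(x.max())
        if spec.df == 1:
            # plain linear term; keeps the double-GLM collapse exact
            self.linear = True
            self.ncols = 1
            self.penalty = np.zeros((1, 1))
            return
        self.linear = False
        k = spec.degree
        n_interior = max(spec.basis_dim - k - 1, 0)
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        self.knots = np.concatenate(
            [np.full(k + 1, self.lo), interior, np.full(k + 1, self.hi)]
        )
        m = len(self.knots) - k - 1  # basis dimension
        B = self._raw(x)
        c = B.sum(axis=0)
        self.Z = null_space(c[None, :])  # (m, m-1)
        S = self._curvature_penalty(m)
        self.penalty = self.Z.T @ S @ self.Z
        self.ncols = self.Z.shape[1]

    def _curvature_penalty(self, m: int) -> np.ndarray:
        """Integrated squared second derivative, int f''(x)^2 dx.

        For cubic B-splines f'' is piecewise linear, so two-point
        Gauss-Legendre per knot span integrates the products exactly; the
        null space is exactly the linear functions, which makes the
        infinite-penalty limit a plain linear term.
        """
        k = self.spec.degree
        spans = np.unique(self.knots[k:-k] if k > 0 else self.knots)
        gl_x = np.array([-1.0, 1.0]) / math.sqrt(3.0)
        weights = np.empty(0)
        pts_all = []
        for lo, hi in zip(spans[:-1], spans[1:]):
            half = 0.5 * (hi - lo)
            pts = 0.5 * (lo + hi) + half * gl_x
            pts_all.append(pts)
            weights = np.append(weights, np.full(2, half))
        pts_all = np.concatenate(pts_all) if pts_all else np.empty(0)
        basis2 = np.column_stack(
            [
                BSpline(self.knots, np.eye(m)[j], k).derivative(2)(pts_all)
                for j in range(m)
            ]
        )  # (n_pts, m)
        S = (basis2 * weights[:, None]).T @ basis2
        # int f''^2 dx scales as range^-3 under affine rescaling of x;
        # multiplying by range^3 makes lambda dimensionless, so predictions
        # are exactly invariant to affine covariate rescaling
        return S * (self.hi - self.lo) ** 3

    def _raw(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.lo, self.hi)
        M = BSpline.design_matrix(xc, self.knots, self.spec.degree)
        return np.asarray(M.todense())

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.linear:
            return np.asarray(x, float)[:, None]
        return self._raw(np.asarray(x, float)) @ self.Z


@dataclass
class AdditiveFit:
    """Fitted double GAM: coefficients, smooths, GCV, effective df, and the
    dispersion submodel."""

    coef: np.ndarray
    coef_names: list
    smooth_bases: list  # list[_SmoothBasis]
    smooth_names: list
    parametric: list
    lambdas: np.ndarray
    gcv: float
    edf_per_smooth: dict
    edf_total: float
    deviance: float
    nonlinearity: dict  # {"stat", "df", "p_value"}
    disp_fit: Optional[GLMFit]
    phi: np.ndarray
    outer_iterations: int
    converged: bool
    _blocks: list  # column index arrays per smooth

    def mean_design(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(data))]
        for c in self.parametric:
            cols.append(data[c].to_numpy(float))
        X = np.column_stack(cols)
        mats = [X] + [
            b.transform(data[name].to_numpy(float))
            for b, name in zip(self.smooth_bases, self.smooth_names)
        ]
        return np.hstack(mats)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Marginal probabilities from the additive mean submodel."""
        return expit(self.mean_design(data) @ self.coef)

    def smooth_table(self, name: str, n_grid: int = 101) -> pd.DataFrame:
        """(x, f_hat(x)) table of one fitted smooth over its observed range."""
        i = self.smooth_names.index(name)
        basis = self.smooth_bases[i]
        xg = np.linspace(basis.lo, basis.hi, n_grid)
        f = basis.transform(xg) @ self.coef[self._blocks[i]]
        return pd.DataFrame({name: xg, "fit": f})


def gcv_score(deviance: float, n: int, edf: float) -> float:
    """Generalized cross validation: n * Deviance / (n - tr(H))^2.

    Returns +inf when the effective df reaches the sample size.
    """
    if edf >= n:
        return float("inf")
    return float(n * deviance / (n - edf) ** 2)


def _pirls(X, y, w_prior, penalty, max_iter=60, tol=1e-8):
    """Penalized IRLS for the binomial/logit additive model.

    Returns (coef, deviance, edf_diag, converged); edf_diag is the diagonal
    of (X'WX + P)^-1 X'WX, whose trace is tr(H).
    """
    n, p = X.shape
    beta = np.zeros(p)
    mu = np.clip((y + 0.5) / 2.0, 1e-6, 1 - 1e-6)
    eta = np.log(mu / (1 - mu))
    dev = np.inf
    converged = False
    for _ in range(max_iter):
        w = w_prior * np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / np.clip(mu * (1 - mu), 1e-10, None)
        XtW = X.T * w
        A = XtW @ X + penalty
        try:
            beta_new = np.linalg.solve(A, XtW @ z)
        except np.linalg.LinAlgError:
            warnings.warn("singular penalized system; adding ridge floor", RuntimeWarning)
            A = A + 1e-8 * np.eye(p)
            beta_new = np.linalg.solve(A, XtW @ z)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        dev = float(np.sum(w_prior * unit_deviance(y, mu)))
        if delta < tol:
            converged = True
            break
    w = w_prior * np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = (X.T * w) @ X
    A = XtWX + penalty
    edf_diag = np.diag(np.linalg.solve(A, XtWX))
    return beta, dev, edf_diag, converged


def _assemble(data, parametric, smooth_bases, smooth_names):
    n = len(data)
    cols = [np.ones(n)]
    for c in parametric:
        cols.append(data[c].to_numpy(float))
    X0 = np.column_stack(cols)
    blocks = []
    mats = [X0]
    start = X0.shape[1]
    for b, name in zip(smooth_bases, smooth_names):
        M = b.transform(data[name].to_numpy(float))
        mats.append(M)
        blocks.append(np.arange(start, start + M.shape[1]))
        start += M.shape[1]
    return np.hstack(mats), blocks


def _penalty_matrix(p, blocks, bases, lambdas):
    P = np.zeros((p, p))
    for idx, b, lam in zip(blocks, bases, lambdas):
        P[np.ix_(idx, idx)] = lam * b.penalty
    return P


def fit_double_gam(
    cohort: CohortTable,
    smooths: Sequence[SmoothSpec],
    parametric: Sequence[str],
    disp_spec: Optional[DispersionSpec] = None,
    tol: float = 1e-5,
    max_outer: int = 25,
    selection: str = "gcv",
) -> AdditiveFit:
    """Fit the double GAM.

    Smoothing penalties are selected on the initial (unit-weight) mean fit —
    one pass of per-smooth grid search by GCV (``selection='gcv'``) or by
    matching each smooth's target effective df (``selection='edf'``) — and
    held fixed while the mean and dispersion submodels alternate to a joint
    fixed point, as in the double GLM.
    """
    data = cohort.data
    if disp_spec is None:
        disp_spec = DispersionSpec(covariates=[], family="gaussian", link="identity")
    disp_spec.validate(list(data.columns))
    y = data["y"].to_numpy(float)
    n = len(data)

    bases = [_SmoothBasis(data[s.name].to_numpy(float), s) for s in smooths]
    names = [s.name for s in smooths]
    X, blocks = _assemble(data, parametric, smooth_bases=bases, smooth_names=names)
    p = X.shape[1]
    w1 = np.ones(n)

    # --- penalty selection on the unit-weight fit ---
    lambdas = np.array([np.median(s.penalty_grid) if not b.linear else 0.0
                        for s, b in zip(smooths, bases)])
    for i, (s, b) in enumerate(zip(smooths, bases)):
        if b.linear:
            continue
        best = (np.inf, lambdas[i])
        for lam in s.penalty_grid:
            trial = lambdas.copy()
            trial[i] = lam
            P = _penalty_matrix(p, blocks, bases, trial)
            _, dev, edf_diag, _ = _pirls(X, y, w1, P)
            edf_tot = float(edf_diag.sum())
            if selection == "gcv":
                score = gcv_score(dev, n, edf_tot)
            else:  # match target effective df
                score = abs(float(edf_diag[blocks[i]].sum()) - s.df)
            if score < best[0]:
                best = (score, lam)
        lambdas[i] = best[1]

    P = _penalty_matrix(p, blocks, bases, lambdas)

    # --- alternate mean and dispersion submodels at fixed penalties ---
    phi = np.ones(n)
    coef, dev, edf_diag, _ = _pirls(X, y, w1, P)
    disp_fit = None
    prev = coef.copy()
    converged = False
    outer = 0
    for outer in range(1, max_outer + 1):
        mu = np.clip(expit(X @ coef), 1e-12, 1 - 1e-12)
        d = np.clip(unit_deviance(y, mu), 1e-10, None)
        ddata = data.copy()
        ddata["_log_disp_response"] = np.log(d)
        disp_fit = irls_fit(
            ddata,
            GLMSpec(
                family="gaussian",
                link="identity",
                response="_log_disp_response",
                covariates=list(disp_spec.covariates),
            ),
        )
        phi = np.clip(np.exp(disp_fit.eta), 1e-8, 1e8)
        coef, dev, edf_diag, _ = _pirls(X, y, 1.0 / phi, P)
        delta = np.max(np.abs(coef - prev))
        prev = coef.copy()
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("double GAM outer loop did not converge", RuntimeWarning)

    edf_total = float(edf_diag.sum())
    edf_per_smooth = {
        name: float(edf_diag[idx].sum()) for name, idx in zip(names, blocks)
    }
    # report deviance/GCV on the plain (unweighted) Bernoulli scale so they
    # are comparable across dispersion weightings
    mu_final = np.clip(expit(X @ coef), 1e-12, 1 - 1e-12)
    dev = float(unit_deviance(y, mu_final).sum())
    gcv = gcv_score(dev, n, edf_total)

    # --- nonlinearity: penalized fit vs nested linear-in-smooths fit ---
    lin_cols = list(parametric) + names
    lin_fit = irls_fit(
        data,
        GLMSpec(
            family="binomial",
            link="logit",
            response="y",
            covariates=lin_cols,
            prior_weights=1.0 / phi,
        ),
    )
    dev_lin = float(unit_deviance(y, np.clip(lin_fit.mu, 1e-12, 1 - 1e-12)).sum())
    ddev = max(dev_lin - dev, 0.0)
    df_nl = max(sum(edf_per_smooth[nm] - 1.0 for nm in names), 1e-8)
    nonlinearity = {
        "stat": ddev,
        "df": df_nl,
        "p_value": float(stats.chi2.sf(ddev, df_nl)),
    }

    coef_names = (
        ["Intercept"]
        + list(parametric)
        + [f"{nm}[{k}]" for nm, idx in zip(names, blocks) for k in range(len(idx))]
    )
    return AdditiveFit(
        coef=coef,
        coef_names=coef_names,
        smooth_bases=bases,
        smooth_names=names,
        parametric=list(parametric),
        lambdas=lambdas,
        gcv=gcv,
        edf_per_smooth=edf_per_smooth,
        edf_total=edf_total,
        deviance=dev,
        nonlinearity=nonlinearity,
        disp_fit=disp_fit,
        phi=phi,
        outer_iterations=outer,
        converged=converged,
        _blocks=blocks,
    )
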