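"""Logistic GLMM with correlated random intercept and random slope.

Subject-specific model for individual i in community j:

    logit(p_ij) = x_ij' beta + gamma_0j + gamma_1j z_ij,
    (gamma_0j, gamma_1j) ~ N(0, [[delta0^2, sigma01], [sigma01, delta1^2]]),

maximized by adaptive Gauss-Hermite quadrature (order 1 = Laplace) around
per-community posterior modes found by an inner Newton solve, with an outer
quasi-Newton search over the fixed effects and the log-Cholesky factor of
the random-effect covariance (which keeps the estimate positive
semi-definite by construction).

Also provides the unconditional-model ICC screen: an intercept-only random
intercept fit and the latent-threshold formula
icc = delta0^2 / (delta0^2 + pi^2 / 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from .cohort import COMMUNITY_COL, CohortTable
from .glm import GLMSpec, irls_fit

__all__ = [
    "RandomEffectsSpec",
    "GLMMFit",
    "ICCResult",
    "fit_glmm",
    "icc_unconditional",
    "conditional_predict",
]

ICC_DECISION_THRESHOLD = 0.05  # conventional "large enough to matter" screen
_BOUNDARY_TOL = 1e-4


@dataclass
class RandomEffectsSpec:
    """Random-effect structure: grouping column and optional random-slope
    covariate (unstructured 2x2 covariance when a slope is present)."""

    group: str = COMMUNITY_COL
    slope: Optional[str] = "arrested"


@dataclass
class GLMMFit:
    params: pd.Series  # fixed effects
    bse: pd.Series
    pvalues: pd.Series
    delta0_sq: float
    delta1_sq: Optional[float]
    sigma01: Optional[float]
    vc_se: dict  # standard errors of the covariance parameters
    vc_pvalues: dict
    ranef: pd.DataFrame  # empirical Bayes modes per community
    loglik: float
    quad_order: int
    converged: bool
    boundary: bool
    fixed_names: list
    re_spec: RandomEffectsSpec
    n_obs: int
    n_groups: int

    def covariance_matrix(self) -> np.ndarray:
        if self.delta1_sq is None:
            return np.array([[self.delta0_sq]])
        return np.array(
            [[self.delta0_sq, self.sigma01], [self.sigma01, self.delta1_sq]]
        )


@dataclass
class ICCResult:
    """Unconditional-model ICC on the latent-threshold scale."""

    delta0_sq: float
    icc: float
    warrants_correlated_model: bool
    fit: GLMMFit


class _Problem:
    """Padded per-community arrays and the marginal log-likelihood."""

    def __init__(self, data: pd.DataFrame, fixed: Sequence[str], re: RandomEffectsSpec):
        if re.group not in data.columns:
            raise ValueError(f"grouping column {re.group!r} not in cohort")
        codes, uniques = pd.factorize(data[re.group], sort=True)
        J = len(uniques)
        if J < 2:
            raise ValueError(f"grouping column {re.group!r} has < 2 levels")
        self.groups = uniques
        self.J = J
        self.d = 2 if re.slope is not None else 1
        y = data["y"].to_numpy(float)
        n = len(y)
        P = len(fixed) + 1
        Xcols = [np.ones(n)] + [data[c].to_numpy(float) for c in fixed]
        X = np.column_stack(Xcols)
        z = data[re.slope].to_numpy(float) if re.slope is not None else np.zeros(n)
        if re.slope is not None:
            varies = pd.DataFrame({"g": codes, "z": z}).groupby("g")["z"].nunique()
            if not (varies > 1).any():
                raise ValueError(
                    f"slope covariate {re.slope!r} does not vary within any group"
                )

        sizes = np.bincount(codes, minlength=J)
        nmax = int(sizes.max())
        self.yp = np.zeros((J, nmax))
        self.Xp = np.zeros((J, nmax, P))
        self.zp = np.zeros((J, nmax))
        self.mask = np.zeros((J, nmax))
        pos = np.zeros(J, dtype=int)
        for i in range(n):
            j = codes[i]
            k = pos[j]
            self.yp[j, k] = y[i]
            self.Xp[j, k] = X[i]
            self.zp[j, k] = z[i]
            self.mask[j, k] = 1.0
            pos[j] += 1
        self.P = P
        self.n = n
        self.codes = codes
        self._u = np.zeros((J, 2))

    # ---- covariance parameterization (log-Cholesky) ----
    def sigma_from_theta(self, theta):
        if self.d == 1:
            v = math.exp(2.0 * theta[0])
            return np.array([[v]])
        a, b, c = theta
        l11, l22 = math.exp(a), math.exp(c)
        return np.array(
            [
                [l11 * l11, b * l11],
                [b * l11, b * b + l22 * l22],
            ]
        )

    def _modes(self, off, Si, tol=1e-10, max_iter=100):
        """Vectorized per-community Newton solve for the random-effect modes."""
        u = self._u.copy()
        yp, zp, mask = self.yp, self.zp, self.mask
        for _ in range(max_iter):
            eta = off + u[:, [0]] + u[:, [1]] * zp
            p = expit(eta)
            r = mask * (yp - p)
            g0 = r.sum(1) - (Si[0, 0] * u[:, 0] + Si[0, 1] * u[:, 1])
            g1 = (r * zp).sum(1) - (Si[1, 0] * u[:, 0] + Si[1, 1] * u[:, 1])
            w = mask * p * (1.0 - p)
            H00 = w.sum(1) + Si[0, 0]
            H01 = (w * zp).sum(1) + Si[0, 1]
            H11 = (w * zp * zp).sum(1) + Si[1, 1]
            if self.d == 1:
                du0 = g0 / H00
                du1 = np.zeros_like(du0)
            else:
                det = H00 * H11 - H01 * H01
                du0 = (H11 * g0 - H01 * g1) / det
                du1 = (H00 * g1 - H01 * g0) / det
            step = np.maximum(np.abs(du0), np.abs(du1))
            scale = np.where(step > 4.0, 4.0 / np.maximum(step, 1e-300), 1.0)
            u[:, 0] += scale * du0
            u[:, 1] += scale * du1
            if step.max() < tol:
                break
        self._u = u.copy()
        return u

    def _h(self, off, u0, u1, Si, logdet_sigma):
        """Joint log density h(u) = loglik_j(u) + log prior(u), vectorized.

        u0/u1 may carry an extra quadrature-node axis before the row axis.
        """
        eta = off + u0 + u1 * self.zp
        ll = (self.mask * (self.yp * eta - np.logaddexp(0.0, eta))).sum(-1)
        quad = (
            Si[0, 0] * u0[..., 0] ** 2
            + 2.0 * Si[0, 1] * u0[..., 0] * u1[..., 0]
            + Si[1, 1] * u1[..., 0] ** 2
        )
        return ll - 0.5 * quad - 0.5 * self.d * math.log(2 * math.pi) - 0.5 * logdet_sigma

    def loglik(self, beta, theta, quad_order=1):
        sigma = self.sigma_from_theta(theta)
        d = self.d
        if d == 1:
            det_s = sigma[0, 0]
            Si = np.array([[1.0 / max(sigma[0, 0], 1e-12), 0.0], [0.0, 0.0]])
            logdet = math.log(max(sigma[0, 0], 1e-300))
        else:
            det_s = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
            det_s = max(det_s, 1e-12)
            Si = (
                np.array(
                    [[sigma[1, 1], -sigma[0, 1]], [-sigma[0, 1], sigma[0, 0]]]
                )
                / det_s
            )
            logdet = math.log(det_s)

        off = np.einsum("jnp,p->jn", self.Xp, beta)
        u = self._modes(off, Si)

        # curvature at the mode
        eta = off + u[:, [0]] + u[:, [1]] * self.zp
        p = expit(eta)
        w = self.mask * p * (1.0 - p)
        A00 = w.sum(1) + Si[0, 0]
        A01 = (w * self.zp).sum(1) + Si[0, 1]
        A11 = (w * self.zp * self.zp).sum(1) + Si[1, 1]
        if d == 1:
            logdetA = np.log(A00)
        else:
            logdetA = np.log(A00 * A11 - A01 * A01)

        h_mode = self._h(off, u[:, [0]], u[:, [1]], Si, logdet)

        if quad_order <= 1:
            ll = h_mode + 0.5 * d * math.log(2 * math.pi) - 0.5 * logdetA
            return float(ll.sum())

        # adaptive Gauss-Hermite around the mode
        xg, wg = np.polynomial.hermite.hermgauss(quad_order)
        if d == 1:
            nodes = xg[:, None]  # (Q, 1)
            logw = np.log(wg) + xg**2
        else:
            X1, X2 = np.meshgrid(xg, xg, indexing="ij")
            nodes = np.column_stack([X1.ravel(), X2.ravel()])  # (Q, 2)
            W1, W2 = np.meshgrid(wg, wg, indexing="ij")
            logw = np.log(W1.ravel() * W2.ravel()) + (nodes**2).sum(1)

        # Cholesky of A per community, then u_k = mode + sqrt(2) * A^{-T/2} x_k
        l11 = np.sqrt(A00)
        if d == 1:
            t0 = nodes[:, 0][:, None] / l11[None, :]  # (Q, J)
            t1 = np.zeros_like(t0)
        else:
            l21 = A01 / l11
            l22 = np.sqrt(np.maximum(A11 - l21**2, 1e-12))
            t1 = nodes[:, 1][:, None] / l22[None, :]
            t0 = (nodes[:, 0][:, None] - l21[None, :] * t1) / l11[None, :]
        u0 = u[:, 0][None, :] + math.sqrt(2.0) * t0  # (Q, J)
        u1 = u[:, 1][None, :] + math.sqrt(2.0) * t1

        hvals = self._h(
            off[None, :, :],
            u0[:, :, None],
            u1[:, :, None],
            Si,
            logdet,
        )  # (Q, J)
        ll = (
            0.5 * d * math.log(2.0)
            - 0.5 * logdetA
            + logsumexp(hvals + logw[:, None], axis=0)
        )
        return float(ll.sum())


def _neg_loglik_factory(prob: _Problem, quad_order: int):
    P = prob.P

    def f(x):
        return -prob.loglik(x[:P], x[P:], quad_order=quad_order)

    return f


def _numeric_hessian(f, x, h=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    hs = h * (1.0 + np.abs(x))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = hs[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / hs[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * hs[i] * hs[j])
    return H


def fit_glmm(
    cohort: CohortTable,
    fixed: Sequence[str],
    re: Optional[RandomEffectsSpec] = None,
    quad_order: int = 7,
    compute_se: bool = True,
) -> GLMMFit:
    """Maximize the Laplace/adaptive-quadrature marginal likelihood.

    ``quad_order=1`` is the Laplace approximation; the default order 7 refines
    it.  Variance components sitting at (near) zero are reported with the
    ``boundary`` flag rather than raised as errors.
    """
    if re is None:
        re = RandomEffectsSpec()
    data = cohort.data
    prob = _Problem(data, fixed, re)
    P = prob.P

    start_mean = irls_fit(
        data, GLMSpec(family="binomial", link="logit", response="y", covariates=list(fixed))
    )
    beta0 = start_mean.params.to_numpy()
    theta0 = np.full(3 if prob.d == 2 else 1, math.log(0.3))
    if prob.d == 2:
        theta0[1] = 0.0
    x0 = np.concatenate([beta0, theta0])

    f = _neg_loglik_factory(prob, quad_order)
    bounds = [(None, None)] * P
    if prob.d == 2:
        bounds += [(-7.0, 4.0), (-8.0, 8.0), (-7.0, 4.0)]
    else:
        bounds += [(-7.0, 4.0)]
    res = optimize.minimize(
        f,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    xhat = res.x
    beta_hat, theta_hat = xhat[:P], xhat[P:]
    sigma = prob.sigma_from_theta(theta_hat)

    names = ["Intercept"] + list(fixed)
    if compute_se:
        H = _numeric_hessian(f, xhat)
        try:
            cov = np.linalg.pinv(H)
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = np.full((len(xhat), len(xhat)), np.nan)
        var = np.diag(cov).copy()
        var[var < 0] = np.nan
        bse = np.sqrt(var[:P])
        # delta method: covariance parameters from log-Cholesky coordinates
        if prob.d == 2:
            a, b, c = theta_hat
            Jg = np.array(
                [
                    [2.0 * math.exp(2 * a), 0.0, 0.0],
                    [b * math.exp(a), math.exp(a), 0.0],
                    [0.0, 2.0 * b, 2.0 * math.exp(2 * c)],
                ]
            )
            cov_th = cov[P:, P:]
            cov_vc = Jg @ cov_th @ Jg.T
            vc_se = {
                "delta0_sq": math.sqrt(max(cov_vc[0, 0], 0.0)),
                "sigma01": math.sqrt(max(cov_vc[1, 1], 0.0)),
                "delta1_sq": math.sqrt(max(cov_vc[2, 2], 0.0)),
            }
        else:
            a = theta_hat[0]
            se_v = 2.0 * math.exp(2 * a) * math.sqrt(max(cov[P, P], 0.0))
            vc_se = {"delta0_sq": se_v}
    else:
        bse = np.full(P, np.nan)
        vc_se = {}

    loglik = -f(xhat)  # evaluated last so the mode cache reflects the optimum

    zvals = np.divide(beta_hat, bse, out=np.zeros(P), where=np.nan_to_num(bse) > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))
    vc_est = {"delta0_sq": float(sigma[0, 0])}
    if prob.d == 2:
        vc_est["delta1_sq"] = float(sigma[1, 1])
        vc_est["sigma01"] = float(sigma[0, 1])
    vc_p = {}
    for k, v in vc_est.items():
        se = vc_se.get(k, np.nan)
        vc_p[k] = float(2.0 * stats.norm.sf(abs(v) / se)) if se and se > 0 else float("nan")

    ranef = pd.DataFrame(
        prob._u[:, : prob.d],
        index=pd.Index(prob.groups, name=re.group),
        columns=["gamma0", "gamma1"][: prob.d],
    )
    boundary = sigma[0, 0] < _BOUNDARY_TOL or (
        prob.d == 2 and sigma[1, 1] < _BOUNDARY_TOL
    )
    return GLMMFit(
        params=pd.Series(beta_hat, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        delta0_sq=float(sigma[0, 0]),
        delta1_sq=float(sigma[1, 1]) if prob.d == 2 else None,
        sigma01=float(sigma[0, 1]) if prob.d == 2 else None,
        vc_se=vc_se,
        vc_pvalues=vc_p,
        ranef=ranef,
        loglik=loglik,
        quad_order=quad_order,
        converged=bool(res.success),
        boundary=bool(boundary),
        fixed_names=list(fixed),
        re_spec=re,
        n_obs=prob.n,
        n_groups=prob.J,
    )


def profile_loglik(
    cohort: CohortTable,
    fixed: Sequence[str],
    re: RandomEffectsSpec,
    beta: np.ndarray,
    sigma: np.ndarray,
    quad_order: int = 7,
) -> float:
    """Approximate marginal log-likelihood at user-supplied parameters."""
    prob = _Problem(cohort.data, fixed, re)
    if prob.d == 1:
        theta = np.array([0.5 * math.log(max(sigma[0, 0], 1e-12))])
    else:
        L = np.linalg.cholesky(sigma + 1e-12 * np.eye(2))
        theta = np.array([math.log(L[0, 0]), L[1, 0], math.log(L[1, 1])])
    return prob.loglik(np.asarray(beta, float), theta, quad_order=quad_order)


def icc_unconditional(cohort: CohortTable, quad_order: int = 7) -> ICCResult:
    """Intercept-only random-intercept fit and the latent-threshold ICC.

    icc = delta0^2 / (delta0^2 + pi^2/3); flagged as warranting a correlated
    model when icc exceeds 0.05.
    """
    fit = fit_glmm(
        cohort,
        fixed=[],
        re=RandomEffectsSpec(group=COMMUNITY_COL, slope=None),
        quad_order=quad_order,
        compute_se=False,
    )
    icc = latent_threshold_icc(fit.delta0_sq)
    return ICCResult(
        delta0_sq=fit.delta0_sq,
        icc=icc,
        warrants_correlated_model=icc > ICC_DECISION_THRESHOLD,
        fit=fit,
    )


def latent_threshold_icc(delta0_sq: float) -> float:
    """delta0^2 / (delta0^2 + pi^2/3)."""
    return float(delta0_sq / (delta0_sq + math.pi**2 / 3.0))


def conditional_predict(fit: GLMMFit, rows: pd.DataFrame, return_flags: bool = False):
    """Conditional probabilities logit^-1(X beta + gamma0_j + gamma1_j z).

    Rows from communities unseen in fitting get gamma = 0 (population-average
    conditional prediction); set ``return_flags=True`` to also receive the
    mask of such rows.
    """
    X = np.column_stack(
        [np.ones(len(rows))] + [rows[c].to_numpy(float) for c in fit.fixed_names]
    )
    eta = X @ fit.params.to_numpy()
    groups = rows[fit.re_spec.group]
    g0 = fit.ranef["gamma0"].reindex(groups).to_numpy()
    unseen = np.isnan(g0)
    g0 = np.nan_to_num(g0)
    eta = eta + g0
    if fit.re_spec.slope is not None:
        g1 = np.nan_to_num(fit.ranef["gamma1"].reindex(groups).to_numpy())
        eta = eta + g1 * rows[fit.re_spec.slope].to_numpy(float)
    p = expit(eta)
    if return_flags:
        return p, unseen
    return p
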