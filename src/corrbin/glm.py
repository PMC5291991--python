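"""Iteratively reweighted least squares engine for the GLMs the package
builds on: binomial/logit, gamma/log and gaussian/identity, with per-row
prior weights, deviance machinery and the Hosmer-Lemeshow lack-of-fit check.

The engine is deliberately self-contained because the joint mean-dispersion
models re-enter it with dispersion-derived prior weights on every outer
iteration; an external fitting routine would not expose that surface cleanly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "GLMSpec",
    "GLMFit",
    "irls_fit",
    "unit_deviance",
    "hosmer_lemeshow",
    "PerfectSeparationError",
    "RankDeficientError",
]

DEVIANCE_EPS = 1e-10  # probability clip for deviance evaluation


class PerfectSeparationError(RuntimeError):
    pass


class RankDeficientError(np.linalg.LinAlgError):
    pass


@dataclass
class GLMSpec:
    """Family/link/formula description of one GLM.

    Admissible pairs: binomial+logit, gamma+log, gaussian+identity.
    ``covariates`` name columns of the data frame; an intercept is always
    prepended.  ``prior_weights`` are per-row and must be positive.
    """

    family: str = "binomial"
    link: str = "logit"
    response: str = "y"
    covariates: Sequence[str] = field(default_factory=list)
    prior_weights: Optional[np.ndarray] = None

    _ADMISSIBLE = {("binomial", "logit"), ("gamma", "log"), ("gaussian", "identity")}

    def validate(self) -> None:
        if (self.family, self.link) not in self._ADMISSIBLE:
            raise ValueError(
                f"link {self.link!r} not admissible for family {self.family!r}; "
                f"supported: {sorted(self._ADMISSIBLE)}"
            )
        if self.prior_weights is not None and np.any(np.asarray(self.prior_weights) <= 0):
            raise ValueError("prior weights must be strictly positive")


@dataclass
class GLMFit:
    """Fitted GLM: coefficient table, linear predictor, fitted means,
    unit deviances, and convergence metadata."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    eta: np.ndarray
    mu: np.ndarray
    unit_deviances: np.ndarray
    deviance: float
    dispersion: float
    iterations: int
    converged: bool
    spec: GLMSpec

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(data, self.spec.covariates)
        eta = X @ self.params.to_numpy()
        return _inv_link(eta, self.spec.link)

    def to_json_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "link": self.spec.link,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "deviance": float(self.deviance),
            "dispersion": float(self.dispersion),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
        }


def _design_matrix(data: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(data))]
    for c in covariates:
        cols.append(data[c].to_numpy(float))
    return np.column_stack(cols)


def _inv_link(eta: np.ndarray, link: str) -> np.ndarray:
    if link == "logit":
        return expit(eta)
    if link == "log":
        return np.exp(eta)
    return eta


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if (diag < tol).any():
        bad = [names[i] for i in np.where(diag < tol)[0]]
        raise RankDeficientError(
            f"design matrix is rank deficient; collinear columns include {bad}"
        )


def _family_deviance(y, mu, family):
    if family == "binomial":
        return unit_deviance(y, mu)
    if family == "gamma":
        mu = np.clip(mu, 1e-300, None)
        ys = np.clip(y, 1e-300, None)
        return 2.0 * ((y - mu) / mu - np.log(ys / mu))
    return (y - mu) ** 2


def irls_fit(data: pd.DataFrame, spec: GLMSpec) -> GLMFit:
    """Fit a GLM by iteratively reweighted least squares.

    Convergence when max |coefficient change| < 1e-8 (max 100 iterations).
    Raises ``RankDeficientError`` on a singular design and
    ``PerfectSeparationError`` when a binomial fit diverges.
    """
    spec.validate()
    y = data[spec.response].to_numpy(float)
    X = _design_matrix(data, spec.covariates)
    names = ["Intercept"] + list(spec.covariates)
    _check_rank(X, names)
    n, p = X.shape
    w_prior = (
        np.ones(n) if spec.prior_weights is None else np.asarray(spec.prior_weights, float)
    )

    family, link = spec.family, spec.link
    if family == "binomial":
        mu = (y + 0.5) / 2.0
    elif family == "gamma":
        if np.any(y <= 0):
            raise ValueError("gamma family requires strictly positive responses")
        mu = np.maximum(y, y.mean() * 1e-3)
    else:
        mu = y.astype(float)

    if link == "logit":
        eta = np.log(mu / (1.0 - mu))
    elif link == "log":
        eta = np.log(mu)
    else:
        eta = mu.copy()

    beta = np.zeros(p)
    dev = float(np.sum(w_prior * _family_deviance(y, mu, family)))
    converged = False
    it = 0
    for it in range(1, 101):
        if link == "logit":
            dmu = mu * (1.0 - mu)
            var = mu * (1.0 - mu)
        elif link == "log":
            dmu = mu
            var = mu**2
        else:
            dmu = np.ones(n)
            var = np.ones(n)
        dmu = np.clip(dmu, 1e-10, None)
        w = w_prior * dmu**2 / np.clip(var, 1e-300, None)
        z = eta + (y - mu) / dmu
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)

        # step halving keeps the deviance monotone
        step = beta_new - beta
        for _half in range(20):
            cand = beta + step
            eta_c = X @ cand
            mu_c = _inv_link(eta_c, link)
            if family == "binomial":
                mu_c = np.clip(mu_c, 1e-12, 1.0 - 1e-12)
            dev_c = float(np.sum(w_prior * _family_deviance(y, mu_c, family)))
            if np.isfinite(dev_c) and (dev_c <= dev + 1e-8 or it == 1):
                break
            step *= 0.5
        delta = np.max(np.abs(cand - beta))
        beta, eta, mu, dev = cand, eta_c, mu_c, dev_c
        if family == "binomial" and np.max(np.abs(eta)) > 20 and delta > 1e-4:
            raise PerfectSeparationError(
                "binomial fit diverging (|linear predictor| > 20): "
                "data are perfectly or quasi-perfectly separated"
            )
        if delta < 1e-8:
            converged = True
            break
    if not converged and family == "binomial" and np.max(np.abs(eta)) > 15:
        raise PerfectSeparationError(
            "binomial fit failed to converge with a diverging linear predictor: "
            "data are perfectly or quasi-perfectly separated"
        )

    # model-based covariance from the final weights
    if link == "logit":
        w_info = w_prior * mu * (1.0 - mu)
    elif link == "log":
        w_info = w_prior * np.ones(n)  # gamma/log: (dmu/deta)^2 / V = mu^2/mu^2
    else:
        w_info = w_prior
    XtWX = (X * w_info[:, None]).T @ X
    cov_unscaled = np.linalg.inv(XtWX)
    if family == "binomial":
        phi = 1.0
    elif family == "gamma":
        pearson = np.sum(w_prior * (y - mu) ** 2 / mu**2)
        phi = pearson / max(n - p, 1)
    else:
        phi = float(np.sum(w_prior * (y - mu) ** 2) / max(n - p, 1))
    cov = cov_unscaled * phi
    bse = np.sqrt(np.diag(cov))
    zvals = np.divide(beta, bse, out=np.zeros_like(beta), where=bse > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))

    ud = w_prior * _family_deviance(y, mu, family)
    return GLMFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        eta=eta,
        mu=mu,
        unit_deviances=ud,
        deviance=float(ud.sum()),
        dispersion=float(phi),
        iterations=it,
        converged=converged,
        spec=spec,
    )


def unit_deviance(y: np.ndarray, p: np.ndarray, eps: float = DEVIANCE_EPS) -> np.ndarray:
    """Bernoulli unit deviance -2[y ln p + (1-y) ln(1-p)].

    Probabilities at 0 or 1 are clipped to [eps, 1-eps] with a warning.
    """
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        warnings.warn(
            f"probabilities at the boundary clipped to [{eps}, 1-{eps}] "
            "for deviance evaluation",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.clip(p, eps, 1.0 - eps)
    return -2.0 * (y * np.log(p) + (1.0 - y) * np.log1p(-p))


def hosmer_lemeshow(y: np.ndarray, p: np.ndarray, groups: int = 10):
    """Hosmer-Lemeshow deciles-of-risk lack-of-fit test.

    Rows are sorted by (p, original index) with a stable sort, split into
    ``groups`` near-equal bins, and X^2 = sum (O - E)^2 / (E (1 - pbar)) is
    referred to chi-square with groups-2 degrees of freedom.  Bins whose
    expected count is zero are merged into their neighbour.
    """
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    if y.shape != p.shape:
        raise ValueError("y and p must have the same length")
    if groups < 2:
        raise ValueError("need at least 2 groups")
    order = np.argsort(p, kind="stable")
    idx_groups = [g for g in np.array_split(order, groups) if g.size]

    # merge groups with degenerate expected counts into the previous one
    merged = []
    for g in idx_groups:
        e1 = p[g].sum()
        e0 = (1.0 - p[g]).sum()
        if merged and (e1 <= 0.0 or e0 <= 0.0):
            merged[-1] = np.concatenate([merged[-1], g])
        else:
            merged.append(g)
    if len(merged) < len(idx_groups):
        warnings.warn("merged Hosmer-Lemeshow groups with zero expected count", RuntimeWarning)

    x2 = 0.0
    for g in merged:
        ng = g.size
        obs = y[g].sum()
        exp = p[g].sum()
        pbar = exp / ng
        denom = exp * (1.0 - pbar)
        if denom <= 0:
            continue
        x2 += (obs - exp) ** 2 / denom
    df = max(len(merged) - 2, 1)
    pval = float(stats.chi2.sf(x2, df))
    return float(x2), pval
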