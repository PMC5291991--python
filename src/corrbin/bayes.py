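"""Bayesian hierarchical logistic regression by Metropolis-within-Gibbs.

Same systematic component as the frequentist GLMM — fixed effects plus a
correlated random intercept and random slope per community — with normal
priors on the regression coefficients (optionally flat) and an
inverse-Wishart prior on the 2x2 random-effect covariance.  The posterior is
proportional to likelihood times prior and is sampled in three blocks:

  (i)   each beta_k by random-walk Metropolis with a per-coordinate scale
        adapted (Robbins-Monro) during burn-in and frozen afterwards;
  (ii)  each community's (gamma_0j, gamma_1j) by random-walk Metropolis,
        all communities updated in parallel (their full conditionals are
        independent given beta and the covariance);
  (iii) the covariance matrix by its conjugate inverse-Wishart full
        conditional given the realized community effects.

Under flat coefficient priors the posterior mode coincides with the maximum
likelihood surface, which is the basis of the Bayes-vs-ML agreement checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .glm import GLMSpec, PerfectSeparationError, irls_fit
from .glmm import RandomEffectsSpec

__all__ = ["PriorSpec", "PosteriorSample", "run_mcmc", "posterior_summary", "predict"]

VC_NAMES = ["var[Intercept]", "var[Arrested]", "cov[int & Slope]"]


@dataclass
class PriorSpec:
    """Priors: beta_k ~ N(0, beta_scale^2) i.i.d. (None = flat), covariance
    ~ inverse-Wishart(iw_df, iw_scale)."""

    beta_scale: Optional[float] = 10.0
    iw_df: float = 3.0
    iw_scale: np.ndarray = field(default_factory=lambda: 0.1 * np.eye(2))

    def validate(self, d: int) -> None:
        if self.beta_scale is not None and self.beta_scale <= 0:
            raise ValueError("beta prior scale must be positive")
        if self.iw_df <= d - 1:
            raise ValueError("inverse-Wishart df must exceed dimension - 1")
        S = np.asarray(self.iw_scale)[:d, :d]
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("inverse-Wishart scale must be positive definite")


@dataclass
class PosteriorSample:
    """Stored MCMC draws plus chain metadata and diagnostics."""

    beta: np.ndarray  # (chains, draws, P)
    gamma: np.ndarray  # (chains, draws, J, d)
    cov: np.ndarray  # (chains, draws, d*(d+1)//2): d0sq[, d1sq, s01]
    beta_names: list
    groups: np.ndarray
    d: int
    iters: int
    burn_in: int
    thin: int
    seed: int
    acceptance: dict
    rhat: dict
    ess: dict
    converged: bool
    fixed_names: list
    re_spec: RandomEffectsSpec

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    def flat_beta(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def posterior_mean_beta(self) -> pd.Series:
        return pd.Series(self.flat_beta().mean(axis=0), index=self.beta_names)

    def posterior_mean_gamma(self) -> pd.DataFrame:
        g = self.gamma.reshape(-1, *self.gamma.shape[2:]).mean(axis=0)
        cols = ["gamma0", "gamma1"][: self.d]
        return pd.DataFrame(g, index=pd.Index(self.groups, name=self.re_spec.group), columns=cols)

    def to_frame(self) -> pd.DataFrame:
        """One row per stored iteration (all chains stacked), for CSV export."""
        cols = {n: self.flat_beta()[:, i] for i, n in enumerate(self.beta_names)}
        flat_cov = self.cov.reshape(-1, self.cov.shape[-1])
        for i, n in enumerate(VC_NAMES[: flat_cov.shape[1]]):
            cols[n] = flat_cov[:, i]
        return pd.DataFrame(cols)


def _gibbs_cov_draw(rng, gamma, prior: PriorSpec, d: int) -> np.ndarray:
    """Conjugate inverse-Wishart draw given realized community effects."""
    J = gamma.shape[0]
    S0 = np.asarray(prior.iw_scale, float)[:d, :d]
    scale = S0 + gamma[:, :d].T @ gamma[:, :d]
    df = prior.iw_df + J
    draw = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    return np.asarray(draw, float).reshape(d, d)


def run_mcmc(
    cohort: CohortTable,
    fixed: Sequence[str],
    re: Optional[RandomEffectsSpec] = None,
    priors: Optional[PriorSpec] = None,
    iters: int = 20000,
    burn_in: int = 5000,
    chains: int = 2,
    thin: int = 5,
    seed: int = 0,
    fixed_covariance: Optional[np.ndarray] = None,
) -> PosteriorSample:
    """Sample the hierarchical-logistic posterior.

    ``fixed_covariance`` freezes the random-effect covariance (a zero matrix
    removes the random effects entirely, reducing the model to Bayesian
    logistic regression).  Deterministic given ``seed``.
    """
    if re is None:
        re = RandomEffectsSpec()
    if priors is None:
        priors = PriorSpec()
    if iters <= burn_in:
        raise ValueError("iters must exceed burn_in")
    if chains < 2:
        warnings.warn("fewer than 2 chains: split-Rhat diagnostics are weak", RuntimeWarning)

    data = cohort.data
    y = data["y"].to_numpy(float)
    n = len(y)
    X = np.column_stack([np.ones(n)] + [data[c].to_numpy(float) for c in fixed])
    P = X.shape[1]
    beta_names = ["Intercept"] + list(fixed)
    codes, uniques = pd.factorize(data[re.group], sort=True)
    J = len(uniques)
    d = 2 if re.slope is not None else 1
    z = data[re.slope].to_numpy(float) if re.slope is not None else np.zeros(n)
    priors.validate(d)

    no_re = False
    if fixed_covariance is not None:
        fixed_covariance = np.asarray(fixed_covariance, float)[:d, :d]
        no_re = np.allclose(fixed_covariance, 0.0)

    # deterministic, data-driven start: ML logistic fit
    try:
        beta_start = irls_fit(
            data, GLMSpec(family="binomial", link="logit", response="y", covariates=list(fixed))
        ).params.to_numpy()
    except (PerfectSeparationError, np.linalg.LinAlgError):
        beta_start = np.zeros(P)

    n_stored = (iters - burn_in) // thin
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)

    all_beta = np.empty((chains, n_stored, P))
    all_gamma = np.empty((chains, n_stored, J, d))
    all_cov = np.empty((chains, n_stored, 3 if d == 2 else 1))
    acc_beta = np.zeros((chains, P))
    acc_gamma = np.zeros((chains, J))

    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        beta = beta_start + 0.01 * rng.standard_normal(P)
        gamma = np.zeros((J, 2))
        if fixed_covariance is not None:
            Sig = fixed_covariance.copy() if not no_re else np.eye(d)
        else:
            Sig = np.asarray(priors.iw_scale, float)[:d, :d] / max(priors.iw_df - d - 1, 1.0)
            Sig = Sig + 0.05 * np.eye(d)
        Sig_inv = np.linalg.inv(Sig) if not no_re else np.eye(d)

        log_s_beta = np.full(P, np.log(0.1))
        log_s_gamma = np.full(J, np.log(0.3))
        eta_fix = X @ beta
        eta_re = gamma[codes, 0] + gamma[codes, 1] * z
        eta = eta_fix + eta_re
        rowll = y * eta - np.logaddexp(0.0, eta)
        nacc_b = np.zeros(P)
        nacc_g = np.zeros(J)
        stored = 0
        for t in range(1, iters + 1):
            adapt = t <= burn_in
            gain = t ** -0.6

            # --- block (i): fixed effects, coordinate-wise RW Metropolis ---
            for k in range(P):
                step = np.exp(log_s_beta[k]) * rng.standard_normal()
                eta_new = eta + step * X[:, k]
                rowll_new = y * eta_new - np.logaddexp(0.0, eta_new)
                dll = rowll_new.sum() - rowll.sum()
                if priors.beta_scale is not None:
                    b_new = beta[k] + step
                    dll += (beta[k] ** 2 - b_new**2) / (2.0 * priors.beta_scale**2)
                accept = np.log(rng.random()) < dll
                if accept:
                    beta[k] += step
                    eta = eta_new
                    rowll = rowll_new
                    nacc_b[k] += 1
                if adapt:
                    log_s_beta[k] += gain * ((1.0 if accept else 0.0) - 0.44)
            eta_fix = eta - eta_re

            # --- block (ii): community effects, parallel RW Metropolis ---
            if not no_re:
                prop = gamma.copy()
                steps = np.exp(log_s_gamma)[:, None] * rng.standard_normal((J, d))
                prop[:, :d] += steps
                eta_re_new = prop[codes, 0] + prop[codes, 1] * z
                eta_new = eta_fix + eta_re_new
                rowll_new = y * eta_new - np.logaddexp(0.0, eta_new)
                dll_j = np.bincount(codes, weights=rowll_new - rowll, minlength=J)
                gd, pd_ = gamma[:, :d], prop[:, :d]
                dprior = -0.5 * (
                    np.einsum("ji,ik,jk->j", pd_, Sig_inv, pd_)
                    - np.einsum("ji,ik,jk->j", gd, Sig_inv, gd)
                )
                acc = np.log(rng.random(J)) < dll_j + dprior
                nacc_g += acc
                gamma[acc] = prop[acc]
                if acc.any():
                    eta_re = gamma[codes, 0] + gamma[codes, 1] * z
                    eta = eta_fix + eta_re
                    rowll = y * eta - np.logaddexp(0.0, eta)
                if adapt:
                    log_s_gamma += gain * (acc.astype(float) - 0.30)

                # --- block (iii): covariance, conjugate Gibbs ---
                if fixed_covariance is None:
                    Sig = _gibbs_cov_draw(rng, gamma, priors, d)
                    Sig_inv = np.linalg.inv(Sig)

            if t > burn_in and (t - burn_in) % thin == 0:
                all_beta[c, stored] = beta
                all_gamma[c, stored] = gamma[:, :d]
                if d == 2:
                    all_cov[c, stored] = (Sig[0, 0], Sig[1, 1], Sig[0, 1])
                else:
                    all_cov[c, stored] = Sig[0, 0]
                stored += 1

        acc_beta[c] = nacc_b / iters
        acc_gamma[c] = nacc_g / iters

    acceptance = {
        "beta": acc_beta.mean(axis=0),
        "gamma": acc_gamma.mean(axis=0),
    }
    mean_acc = float(np.concatenate([acceptance["beta"], acceptance["gamma"] if not no_re else []]).mean())
    if not 0.1 <= mean_acc <= 0.6:
        warnings.warn(
            f"mean Metropolis acceptance rate {mean_acc:.2f} outside [0.1, 0.6] "
            "after adaptation",
            RuntimeWarning,
        )

    rhat, ess = _diagnostics(all_beta, all_cov, beta_names, d)
    max_rhat = max(rhat.values()) if rhat else np.nan
    converged = bool(np.isfinite(max_rhat) and max_rhat <= 1.1)
    if not converged:
        warnings.warn(f"chains not converged: max split-Rhat = {max_rhat:.3f}", RuntimeWarning)

    return PosteriorSample(
        beta=all_beta,
        gamma=all_gamma,
        cov=all_cov,
        beta_names=beta_names,
        groups=np.asarray(uniques),
        d=d,
        iters=iters,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        acceptance=acceptance,
        rhat=rhat,
        ess=ess,
        converged=converged,
        fixed_names=list(fixed),
        re_spec=re,
    )


def _diagnostics(all_beta, all_cov, beta_names, d):
    import arviz as az

    post = {n: all_beta[:, :, i] for i, n in enumerate(beta_names)}
    for i, n in enumerate(VC_NAMES[: all_cov.shape[-1]]):
        post[n] = all_cov[:, :, i]
    idata = az.from_dict(posterior=post)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rh = az.rhat(idata)
        es = az.ess(idata)
    rhat = {n: float(rh[n].values) for n in post}
    ess = {n: float(es[n].values) for n in post}
    return rhat, ess


def posterior_summary(sample: PosteriorSample) -> pd.DataFrame:
    """Per-parameter posterior mean, SD, 95% credible interval and the
    two-sided tail probability 2*min(Pr(theta>0), Pr(theta<0)) — a Bayesian
    analogue of a p-value, not a frequentist p."""
    if not sample.converged:
        warnings.warn("summarizing a sample whose chains have not converged", RuntimeWarning)
    rows = {}
    flat = sample.flat_beta()
    for i, n in enumerate(sample.beta_names):
        rows[n] = flat[:, i]
    flat_cov = sample.cov.reshape(-1, sample.cov.shape[-1])
    for i, n in enumerate(VC_NAMES[: flat_cov.shape[1]]):
        rows[n] = flat_cov[:, i]
    out = []
    for n, draws in rows.items():
        p_pos = float(np.mean(draws > 0))
        out.append(
            {
                "parameter": n,
                "mean": float(draws.mean()),
                "sd": float(draws.std(ddof=1)),
                "ci_2.5%": float(np.quantile(draws, 0.025)),
                "ci_97.5%": float(np.quantile(draws, 0.975)),
                "tail_prob": float(2.0 * min(p_pos, 1.0 - p_pos)),
            }
        )
    return pd.DataFrame(out).set_index("parameter")


def predict(
    sample: PosteriorSample, rows: pd.DataFrame, method: str = "plugin"
) -> np.ndarray:
    """Conditional smoking probabilities for new rows.

    ``plugin`` uses posterior means of beta and the community effects;
    ``average`` averages expit over the stored draws (posterior predictive
    mean).  Unseen communities get gamma = 0.
    """
    from scipy.special import expit

    X = np.column_stack(
        [np.ones(len(rows))] + [rows[c].to_numpy(float) for c in sample.fixed_names]
    )
    group_pos = {g: i for i, g in enumerate(sample.groups)}
    gidx = np.array([group_pos.get(g, -1) for g in rows[sample.re_spec.group]])
    zrow = (
        rows[sample.re_spec.slope].to_numpy(float)
        if sample.re_spec.slope is not None
        else np.zeros(len(rows))
    )
    seen = gidx >= 0
    if method == "plugin":
        beta = sample.posterior_mean_beta().to_numpy()
        g = sample.posterior_mean_gamma().to_numpy()
        eta = X @ beta
        eta[seen] += g[gidx[seen], 0]
        if sample.d == 2:
            eta[seen] += g[gidx[seen], 1] * zrow[seen]
        return expit(eta)
    if method != "average":
        raise ValueError("method must be 'plugin' or 'average'")
    betas = sample.flat_beta()
    gammas = sample.gamma.reshape(-1, *sample.gamma.shape[2:])
    probs = np.zeros(len(rows))
    for b, g in zip(betas, gammas):
        eta = X @ b
        eta[seen] += g[gidx[seen], 0]
        if sample.d == 2:
            eta[seen] += g[gidx[seen], 1] * zrow[seen]
        probs += expit(eta)
    return probs / len(betas)
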