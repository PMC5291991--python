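"""Double GLM: joint modeling of the mean and the dispersion.

Two interlinked GLMs are fitted by alternating reweighted estimation:

  mean submodel        logit(p_i) = beta_0 + beta_1 X_1 + ... + beta_K X_K
  dispersion submodel  log(phi_i) = gamma_0 + gamma_1 Z_1 + ... + gamma_t Z_t

The Bernoulli unit deviances d_i from the mean submodel are the response of
the dispersion submodel (gamma family, log link); the fitted dispersions
phi_i re-enter the mean submodel as prior weights 1/phi_i.  The loop runs to
a joint fixed point of both coefficient vectors.

For ungrouped binary data the unit deviance is a deterministic function of
the fitted probability, so dispersion-submodel coefficients are
extended-quasi-likelihood heterogeneity scores rather than literal variance
parameters; they are reported exactly as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .glm import GLMFit, GLMSpec, irls_fit

__all__ = ["DispersionSpec", "JointFit", "fit_double_glm", "dispersion_table"]


@dataclass
class DispersionSpec:
    """Dispersion submodel: covariates Z_1..Z_t (t=0 means constant
    dispersion), response kind, and fitting family."""

    covariates: Sequence[str] = field(default_factory=lambda: ["arrested"])
    response_kind: str = "unit_deviance"  # or "squared_pearson"
    family: str = "gamma"  # gamma/log for the double GLM
    link: str = "log"

    def validate(self, available: Sequence[str]) -> None:
        missing = [c for c in self.covariates if c not in available]
        if missing:
            raise ValueError(f"dispersion covariates not in cohort: {missing}")
        if self.response_kind not in ("unit_deviance", "squared_pearson"):
            raise ValueError(f"unknown dispersion response kind {self.response_kind!r}")


@dataclass
class JointFit:
    """Paired mean and dispersion submodel fits with convergence metadata."""

    mean_fit: GLMFit
    disp_fit: GLMFit
    phi: np.ndarray
    outer_iterations: int
    converged: bool
    trace: list  # outer-loop max coefficient change per iteration
    disp_spec: DispersionSpec

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Marginal smoking probabilities from the mean submodel."""
        return self.mean_fit.predict(data)


def _dispersion_response(mean_fit: GLMFit, y: np.ndarray, kind: str) -> np.ndarray:
    # raw (prior-weight-free) residual response: the fitted dispersions must
    # not feed back into their own response
    if kind == "unit_deviance":
        from .glm import unit_deviance

        return unit_deviance(y, np.clip(mean_fit.mu, 1e-12, 1 - 1e-12))
    r2 = (y - mean_fit.mu) ** 2 / np.clip(mean_fit.mu * (1 - mean_fit.mu), 1e-12, None)
    return r2


def fit_double_glm(
    cohort: CohortTable,
    mean_spec: GLMSpec,
    disp_spec: DispersionSpec,
    tol: float = 1e-6,
    max_outer: int = 50,
    alternate: bool = True,
) -> JointFit:
    """Alternating fit of the mean and dispersion submodels.

    ``alternate=False`` performs a single two-stage pass (mean fit, then one
    dispersion fit, then one re-weighted mean fit) instead of iterating to a
    fixed point.
    """
    data = cohort.data
    disp_spec.validate(list(data.columns))
    y = data[mean_spec.response].to_numpy(float)
    n = len(data)

    phi = np.ones(n)
    mean_fit = irls_fit(data, _with_weights(mean_spec, None))
    disp_fit = None
    gamma_prev = None
    beta_prev = mean_fit.params.to_numpy().copy()
    trace = []
    converged = False
    outer = 0
    for outer in range(1, max_outer + 1):
        d = _dispersion_response(mean_fit, y, disp_spec.response_kind)
        if np.all(d < 1e-12):
            raise ValueError("degenerate dispersion response: all unit deviances ~ 0")
        d = np.clip(d, 1e-10, None)
        ddata = data.copy()
        ddata["_disp_response"] = d
        disp_fit = irls_fit(
            ddata,
            GLMSpec(
                family=disp_spec.family,
                link=disp_spec.link,
                response="_disp_response",
                covariates=list(disp_spec.covariates),
            ),
        )
        phi = np.clip(disp_fit.mu, 1e-8, 1e8)
        mean_fit = irls_fit(data, _with_weights(mean_spec, 1.0 / phi))

        beta = mean_fit.params.to_numpy()
        gamma = disp_fit.params.to_numpy()
        delta = np.max(np.abs(beta - beta_prev))
        if gamma_prev is not None:
            delta = max(delta, np.max(np.abs(gamma - gamma_prev)))
        trace.append(float(delta))
        beta_prev, gamma_prev = beta.copy(), gamma.copy()
        if not alternate:
            converged = True
            break
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"double GLM did not reach a joint fixed point in {max_outer} outer "
            "iterations",
            RuntimeWarning,
        )
    return JointFit(
        mean_fit=mean_fit,
        disp_fit=disp_fit,
        phi=phi,
        outer_iterations=outer,
        converged=converged,
        trace=trace,
        disp_spec=disp_spec,
    )


def _with_weights(spec: GLMSpec, w) -> GLMSpec:
    return GLMSpec(
        family=spec.family,
        link=spec.link,
        response=spec.response,
        covariates=list(spec.covariates),
        prior_weights=w,
    )


def dispersion_table(fit: JointFit) -> pd.DataFrame:
    """Coefficient report of the dispersion submodel: one row for the
    intercept and one per dispersion covariate, with Wald z p-values."""
    df = fit.disp_fit
    return pd.DataFrame(
        {
            "estimate": df.params,
            "se": df.bse,
            "p_value": df.pvalues,
        }
    )
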