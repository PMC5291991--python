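# corrbin

Models for **correlated binary outcomes** in clustered survey data, built
around a four-way comparison that matters in practice: when individuals are
nested in communities, should you model the outcome *conditionally* (random
effects in the linear predictor) or *marginally* (an explicit submodel for
the dispersion)?

The motivating application is regular smoking in a large in-home health
survey: ~4,484 adults nested in 132 communities, a binary outcome with ~45%
prevalence, 19 demographic/health/emotional covariates, and prior evidence
that the effect of ever having been **arrested** varies from community to
community.

## The four models

All models share the Bernoulli outcome Y_ij (individual i, community j) and
covariates X_ij1..X_ijK.

**1. Frequentist hierarchical logistic regression** (`corrbin.glmm`) —
subject-specific model with correlated random intercept and random slope:

    logit(p_ij) = β0 + Σk βk X_ijk + γ0j + γ1j Z_ij1,
    (γ0j, γ1j) ~ N(0, [[δ0², σ01], [σ01, δ1²]]),

where Z_ij1 is the arrest indicator.  Maximized by adaptive Gauss–Hermite
quadrature (order 1 = Laplace) over the random effects, with a log-Cholesky
parameterization keeping the covariance positive semi-definite.  Also
supplies the screening step: an intercept-only random-intercept fit and the
latent-threshold intraclass correlation ICC = δ0²/(δ0² + π²/3).

**2. Bayesian hierarchical logistic regression** (`corrbin.bayes`) — the same
systematic component with normal priors on β (optionally flat) and an
inverse-Wishart prior on the random-effect covariance, sampled by
Metropolis-within-Gibbs: coordinate-wise random-walk updates for β,
parallel per-community updates for (γ0j, γ1j), and a conjugate
inverse-Wishart draw for the covariance.  Split-R̂/ESS diagnostics via arviz.

**3. Double GLM** (`corrbin.dglm`) — marginal joint model of mean and
dispersion: a logit mean submodel and a gamma/log dispersion submodel whose
response is the Bernoulli unit deviance d_i from the mean fit,

    logit(p_i) = β0 + Σ βk X_k,      log(φ_i) = γ0 + γ1 Z_1,

alternated to a joint fixed point with the mean submodel re-weighted by
1/φ̂_i.

**4. Double GAM** (`corrbin.dgam`) — the additive variant: penalized cubic
B-spline smooths for continuous covariates in the mean submodel, a
normal/identity dispersion submodel on log d_i, and GCV-selected smoothing,
GCV = n·Deviance/(n − tr H)².

`corrbin.compare` evaluates all four by the design used in the application:
four disjoint 25% validation folds, each model fitted on the complementary
75% and scored by ROC AUC on both partitions.  `corrbin.cohort` generates
synthetic cohorts from the hierarchical model above so every estimator is
testable against known truth.

## Worked example

```python
from corrbin import cohort, glm, glmm, dglm

# a synthetic cohort with the survey's structure (132 communities, n=4484)
params = cohort.default_addhealth_params(seed=1)
tab = cohort.generate(params)
print(f"prevalence: {tab.data.y.mean():.3f}")

# screen: does the clustering warrant a correlated model?
icc = glmm.icc_unconditional(tab)
print(f"ICC = {icc.icc:.3f}  (correlated model warranted: {icc.warrants_correlated_model})")

# double GLM with the arrest indicator in the dispersion submodel
fit = dglm.fit_double_glm(
    tab,
    glm.GLMSpec(covariates=tab.covariate_names),
    dglm.DispersionSpec(covariates=["arrested"]),
)
print(dglm.dispersion_table(fit).round(3))
```

Output (seed 1):

```
prevalence: 0.450
ICC = 0.030  (correlated model warranted: False)
           estimate     se  p_value
Intercept     0.174  0.013    0.000
arrested      0.049  0.019    0.008
```

The generating random-intercept variance (0.099) implies a small ICC, so the
screen reports ~0.03 here; with δ0² = 0.5624 the same screen recovers
ICC ≈ 0.146.  The positive `arrested` dispersion coefficient says the mean
submodel's deviances are systematically larger in the arrested group — the
marginal model's footprint of the community-varying arrest effect that the
hierarchical models capture as δ1².

The same pipeline is scriptable from the shell:

```bash
corrbin simulate --seed 1 --out cohort.csv
corrbin fit --model hier-freq --data cohort.csv --out fit.json
corrbin compare --data cohort.csv --seed 2 --out report/ --fast
```

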