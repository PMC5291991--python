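# Methods

This note records the statistical models corrbin implements, the numerical
choices behind them, what the synthetic cohort generator does and does not
emulate, and the package's known limitations.

## Synthetic cohort generator

`corrbin.cohort.generate` draws from exactly the data-generating process the
hierarchical models assume:

    logit(p_ij) = β0 + Σk βk X_ijk + γ0j + γ1j Z_ij1,
    (γ0j, γ1j) ~ N2(0, [[δ0², σ01], [σ01, δ1²]]),   Y_ij ~ Bernoulli(p_ij).

`default_addhealth_params()` mirrors the published survey composition: 132
communities, ~4,484 individuals, 19 covariates in three groups
(demographic / health / emotional).  The slope coefficients are the
published random-intercept/random-slope estimates (arrested 0.677, drug
1.221, ...), and the random-effect covariance is the published one
(δ0² = 0.099, δ1² = 0.116, σ01 = 0.028).  Binary covariate prevalences use
the published marginal percentages where printed (e.g. 32.4% non-Caucasian,
21.4% lacking insurance, 13.5% childhood mistreatment, 75% alcohol) and 0.5
where not; TV hours/week, age at first drink and household income (in $10k)
are truncated normals with field-plausible centers and ranges; the child
count is Poisson(0.8).  Community sizes come from a multinomial over mildly
heterogeneous Dirichlet(50) weights, with at least one individual per
community.

The published intercept applies to unpublished covariate scalings, so the
generator calibrates its own intercept (frozen at −0.744 after a one-off
numeric calibration) to reproduce the published ~45.2% marginal smoking
prevalence under these covariate marginals.

What the generator does **not** emulate: the survey's two-stage sampling
weights, longitudinal waves, item nonresponse, and any covariate
correlation structure (covariates are drawn independently).  Tests passing
on these cohorts therefore demonstrate correctness of the estimators under
the assumed model, not robustness to the full messiness of real survey
data.

All randomness flows through one `numpy.random.Generator` seeded explicitly;
the realized (γ0j, γ1j) and full parameter set travel with the cohort in a
JSON sidecar so recovery can be checked.

## GLM engine

A self-contained IRLS engine (binomial/logit, gamma/log, gaussian/identity)
with per-row prior weights, because the joint mean–dispersion models re-enter
it each outer iteration with dispersion-derived weights.  Numerical choices:
coefficient tolerance 1e-8, max 100 iterations, step halving to keep the
deviance monotone, and divergence detection (|η| growing past 20 without
coefficient convergence) reported as perfect separation.  Standard errors
are model-based (inverse expected information; Pearson-based dispersion for
the gamma family).  Probabilities are clipped at ε = 1e-10 for deviance
evaluation, with a warning.

The Hosmer–Lemeshow check partitions rows into deciles of risk by a stable
sort on (p, row index), merges bins with zero expected counts into their
neighbour, and refers X² = Σ (O−E)²/(E(1−p̄)) to χ² with g−2 df.

## Double GLM (joint mean and dispersion)

Mean submodel: logistic regression on all covariates.  Dispersion submodel:
gamma GLM with log link whose response is the **raw Bernoulli unit deviance**
d_i = −2[y ln p̂ + (1−y) ln(1−p̂)] from the mean fit (squared Pearson
residuals available as an option).  The two are alternated — mean fit with
prior weights 1/φ̂_i, then dispersion fit of d_i, until the joint coefficient
vector moves less than 1e-6 (max 50 outer iterations); a single two-stage
pass is available by flag.  The gamma family is a quasi-likelihood choice:
the response is positive and the stated link is log; no specific deviance
distribution is assumed.  Wald z p-values are reported for the dispersion
coefficients.

**Interpretation caveat (important).**  For ungrouped binary data the unit
deviance is a deterministic function of p̂_i, with conditional expectation
equal to twice the cross-entropy between the realized and fitted
probabilities.  Consequently unmodeled heterogeneity is visible to the
dispersion submodel *only* through the attenuation of a group's marginal
probability toward 1/2 (entropy inflation): if a group's baseline success
probability is exactly 1/2, latent heterogeneity within it is provably
invisible to this statistic.  Dispersion-submodel coefficients are therefore
extended-quasi-likelihood heterogeneity scores, not literal variance
parameters, and the package's heterogeneity-recovery simulations use a
baseline probability of 0.75 so the attenuation channel carries signal.

## Double GAM

The additive mean submodel uses penalized cubic B-splines for continuous
covariates (≥ 10 distinct values; binary covariates enter parametrically):

- knots at quantiles of the training values, basis dimension 10 by default;
- a sum-to-zero constraint absorbed by reparameterizing each basis onto the
  null space of its column-sum functional (QR), so smooths carry no
  intercept;
- an **integrated squared-second-derivative (curvature) penalty**, evaluated
  exactly by two-point Gauss–Legendre per knot span (f'' is piecewise linear
  for cubic splines).  A coefficient-difference penalty was considered and
  rejected: with quantile-placed knots its null space is not the linear
  functions, so the heavy-penalty limit retains spurious curvature.  The
  curvature penalty's null space is exactly {linear}, and it is normalized
  by range³ so predictions are invariant to affine rescaling of the
  covariate;
- smoothing selected by GCV = n·Deviance/(n − tr H)² over a 25-point
  logarithmic penalty grid (one pass of per-smooth coordinate search);
  selection by target effective df is available (`selection="edf"`, default
  target 3 per smooth).  Penalties are selected on the initial unit-weight
  fit and held fixed while the mean and dispersion submodels alternate,
  so the outer loop has a well-defined fixed point.

The dispersion submodel here is gaussian with identity link on log d_i,
distinct from the gamma/log choice of the double GLM.  Reported deviance and
GCV are computed on the plain (unweighted) Bernoulli scale so they are
comparable across dispersion weightings.  The nonlinearity screen compares
the penalized fit against the nested linear-in-smooths logistic fit under
the same weights, referring the deviance difference to χ² with
Σ(edf_s − 1) df — an approximate reference, adequate as a screen; its level
and power are exercised by simulation in the test suite.

The GCV *value* depends on these normalization conventions; the package
documents its own convention and does not target any externally printed GCV
number.

## Frequentist hierarchical model

The marginal likelihood integrates the bivariate random effects per
community.  Implementation: per-community posterior modes by a vectorized
Newton solve (all communities advanced simultaneously on padded arrays);
adaptive Gauss–Hermite quadrature centered and scaled at the modes, order 7
by default (order 1 is exactly the Laplace approximation); outer L-BFGS-B
over (β, log-Cholesky of the covariance), which keeps the covariance PSD by
construction.  Standard errors come from a central-difference Hessian of the
approximate marginal log-likelihood at the optimum; covariance-parameter
SEs by the delta method from the log-Cholesky coordinates.  Variance
components estimated at (near) zero are reported with a `boundary` flag.
Variance-component p-values are two-sided Wald z on the variance scale; a
boundary-corrected test would roughly halve them, which is documented here
rather than silently applied.

The unconditional screen fits the intercept-only random-intercept model and
reports ICC = δ̂0²/(δ̂0² + π²/3), flagging ICC > 0.05 as warranting a
correlated model.  Predictions for communities unseen at fit time use
γ = 0 (population-average conditional prediction) and are flagged.

## Bayesian hierarchical model

Priors: β_k ~ N(0, τ²) i.i.d. with τ = 10 by default (flat available);
covariance ~ inverse-Wishart(ν = 3, S = 0.1·I), chosen for conjugacy of the
covariance block.  Sampling is Metropolis-within-Gibbs:

1. each β_k by random-walk Metropolis with per-coordinate proposal scales
   adapted by Robbins–Monro toward 0.44 acceptance during burn-in and frozen
   afterwards (so the post-burn-in chain is properly Markov);
2. each community's (γ0j, γ1j) jointly by random-walk Metropolis — the full
   conditionals are independent across communities given (β, Σ), so all
   communities are updated in parallel (target acceptance 0.30);
3. Σ by its conjugate inverse-Wishart full conditional given the realized
   effects.

Defaults are 2 chains × 20,000 iterations, 5,000 burn-in, thinning 5; the
comparison harness uses shorter, explicitly configured runs.  Chains start
from the ML logistic fit (deterministic) plus a small seeded jitter.
Convergence is judged by split-R̂ ≤ 1.1 (arviz) and reported, not enforced.
The summary's "tail probability" column is 2·min(Pr(θ>0), Pr(θ<0)) — a
Bayesian analogue of a two-sided p-value, not a frequentist p.  Predictions
default to plug-in posterior means; full posterior-predictive averaging is a
flag.

## Model comparison

`make_splits` partitions individuals uniformly into four disjoint validation
folds (sizes within 1); "four different times, choosing a different 25%" is
read as a 4-fold partition, with independent re-draws available by flag.
Hierarchical models score validation rows with training-fit community
effects — communities appear in both partitions because splitting is by
individual.  AUC is the rank-sum (Mann–Whitney) concordance with midranks
for ties, O(n log n), verified in tests against the O(n²) pairwise count.
A failing model leaves failed cells and the run continues.  Reports are
bit-reproducible given (cohort, config, seed).

## Problem sizes used in the checks

The published estimates come from restricted microdata, so the package's
checks are property-based on synthetic cohorts: full scale (132 × ~34) for
screening and single fits; 60 communities × 40 for the 20-replicate
fixed-effect coverage study (Laplace, quadrature order 1); 75 × 40 for the
50-replicate dispersion-signal studies (arrest-group latent slope variance
3.0, baseline probability 0.75 — see the detectability caveat above);
n = 800–4,000 for the smoothing studies; 40 × 50 with shortened MCMC for the
four-model AUC parity check.  Seeds are fixed constants chosen up front.

## Known limitations

- Two-level nesting only; no crossed effects, no PQL mode, no survey
  weights.
- Laplace/AGH fixed-effect estimates carry the usual small-cluster
  attenuation; with communities of ~30+ the order-1 and order-7 fits agree
  to three decimals.
- The coordinate-wise Metropolis sampler mixes slowly for strongly
  correlated posteriors; effective sample sizes should be checked via the
  reported ESS before quoting posterior SDs.
- Dispersion-submodel estimates for ungrouped binary data are heterogeneity
  scores (see above), and the double-GLM gamma assumption on a two-point
  deviance response is quasi-likelihood, not literal.
- The GAM nonlinearity screen's χ² reference is approximate; its empirical
  level/power are what the simulations show.
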