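import numpy as np
import pytest

from corrbin import cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (132 communities, ~4,484 rows)."""
    return cohort.generate(cohort.default_addhealth_params(seed=20260929))


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled default cohort: 20 communities x ~50, for fast model fits."""
    p = cohort.default_addhealth_params(seed=42)
    p.n_communities = 20
    p.total_n = 1000
    return cohort.generate(p)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Very small cohort with few covariates for structural checks."""
    p = cohort.default_addhealth_params(seed=7)
    p.n_communities = 12
    p.total_n = 360
    p.covariates = p.covariates[:5]
    keep = {"intercept"} | {c.name for c in p.covariates}
    p.beta = {k: v for k, v in p.beta.items() if k in keep}
    return cohort.generate(p)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
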