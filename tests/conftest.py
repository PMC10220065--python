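import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import strataprs as sp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """25-variant panel: frequencies and a shared log-OR vector."""
    rng = np.random.default_rng(7)
    eafs = rng.uniform(0.1, 0.9, 25)
    beta = rng.normal(0.0, 0.12, 25)
    return eafs, beta


@pytest.fixture(scope="session")
def null_cohort(small_panel):
    """One stratified cohort with identical effects in both strata."""
    eafs, beta = small_panel
    cfg = sp.CohortConfig(
        M=25, eafs=eafs, beta_never=beta, beta_ever=beta,
        n_cases_never=600, n_controls_never=600,
        n_cases_ever=600, n_controls_ever=600, seed=42,
    )
    return sp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_weights(small_panel, null_cohort):
    _, beta = small_panel
    return sp.PrsWeightSet(
        snp_ids=list(null_cohort.snp_ids),
        effect_alleles=list(null_cohort.effect_alleles),
        weights=beta,
    )
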