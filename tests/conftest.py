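import warnings

import pytest

import nightvar as nv
from nightvar import bifactor

# statsmodels MixedLM emits convergence chatter on tiny fixtures
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def cohort2000():
    """Large complete-structure cohort for recovery checks."""
    cfg = nv.default_config(n_persons=2000, seed=0)
    persons, nights, truth = nv.generate_cohort(cfg, return_latents=True)
    return cfg, persons, nights, truth


@pytest.fixture(scope="session")
def cfa2000(cohort2000):
    """Bifactor fit + scores on the large cohort."""
    _, persons, _, _ = cohort2000
    panel = bifactor.aggregate_raters(persons)
    fit = bifactor.fit_bifactor_s1(panel, seed=0)
    return panel, fit


@pytest.fixture(scope="session")
def cohort_small():
    """Small cohort for fast end-to-end runs."""
    cfg = nv.default_config(n_persons=100, seed=5)
    persons, nights = nv.generate_cohort(cfg)
    return cfg, persons, nights
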