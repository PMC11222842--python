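"""Shared fixtures: the default synthetic cohort and its fitted enterotypes."""

import numpy as np
import pytest
from hypothesis import settings

from ileotype import build_default_template, fit_enterotypes, simulate_cohort

settings.register_profile("fixed", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("fixed")

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_template():
    return build_default_template()


@pytest.fixture(scope="session")
def default_cohort(default_template):
    """Default study cohort: 76/67/57 samples, theta=60, seeded."""
    return simulate_cohort(default_template, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def fitted(default_cohort):
    """Enterotypes fitted on the default cohort over k = 2..10."""
    return fit_enterotypes(default_cohort.abundance)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240425)
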