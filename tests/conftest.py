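import numpy as np
import pytest

from icnet import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-respondent synthetic cohort shared across read-only tests."""
    return generate_cohort(default_config(n_per_grade=(20, 20, 20, 20)), seed=101)


@pytest.fixture(scope="session")
def full_cohort():
    """A cohort at the study's grade sizes (454 respondents)."""
    return generate_cohort(default_config(), seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
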