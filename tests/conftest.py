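import numpy as np
import pytest

from calens.cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def study_config():
    """Default generator config with the intercept calibrated by exact
    enumeration to the study's 116/406 event rate."""
    return default_config()


@pytest.fixture(scope="session")
def cohort_2k(study_config):
    return generate_cohort(study_config, 2000, seed=11)


@pytest.fixture(scope="session")
def cohort_small(study_config):
    return generate_cohort(study_config, 300, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
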