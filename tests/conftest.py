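import numpy as np
import pytest

import glaucodrive as gd


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale cohort: 40 glaucoma + 10 controls, fixed seed."""
    return gd.CohortConfig(n_glaucoma=40, n_controls=10, seed=424242)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return gd.generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
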