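import numpy as np
import pytest

from vftk.lexicons import load_default_lexicons
from vftk.synthesis import default_config, generate_cohort


@pytest.fixture(scope="session")
def lexicons():
    return load_default_lexicons()


@pytest.fixture(scope="session")
def small_cohort():
    """A 20+20 cohort at default calibration, shared across tests."""
    return generate_cohort(default_config(seed=7, n_hc=20, n_sh=20))


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size (68 + 58) cohort at default calibration."""
    return generate_cohort(default_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
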