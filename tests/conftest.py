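import numpy as np
import pytest

from msltce.catalogue import load_catalogue
from msltce.synthetic_data import generate_baseline_epi, generate_exposure_survey


@pytest.fixture(scope="session")
def ps():
    return load_catalogue()


@pytest.fixture(scope="session")
def small_fixture():
    """Two-disease, ten-age synthetic baseline: fast enough for end-to-end
    runs at any horizon."""
    epi, mlt = generate_baseline_epi(seed=7, profile="small")
    exposures = generate_exposure_survey(seed=7, ages=epi.ages, profile="small")
    return epi, mlt, exposures


@pytest.fixture(scope="session")
def full_fixture():
    epi, mlt = generate_baseline_epi(seed=7, profile="full")
    exposures = generate_exposure_survey(seed=7, ages=epi.ages, profile="full")
    return epi, mlt, exposures


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
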