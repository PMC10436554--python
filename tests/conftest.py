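import numpy as np
import pytest

from crossmove.synthetic import make_domain_maps, make_population


@pytest.fixture(scope="session")
def population():
    return make_population(6, seed=42)


@pytest.fixture(scope="session")
def domain_maps():
    return make_domain_maps(0, sigma_trial=0.3)


@pytest.fixture(scope="session")
def noiseless_maps():
    return make_domain_maps(0, sigma_trial=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
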