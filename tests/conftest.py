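import numpy as np
import pytest

from wingclines import SyntheticConfig, gen_landmarks, gen_sites


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=11, n_sites=10, n_per_site=6)


@pytest.fixture(scope="session")
def small_sites(small_config):
    sites, temps, truth = gen_sites(small_config)
    return sites, temps, truth


@pytest.fixture(scope="session")
def small_landmarks(small_config, small_sites):
    sites, _, _ = small_sites
    configs, truth = gen_landmarks(sites, small_config)
    return configs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
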