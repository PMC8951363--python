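import numpy as np
import pytest

from venomscale import GeneratorConfig, MCMCSettings, PriorSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset (8 species, 14 measures) with known truth."""
    return generate_dataset(GeneratorConfig(n_species=8, total_measures=14, seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """A dataset at the published shape: 36 species, 62 measures."""
    return generate_dataset(GeneratorConfig(seed=3))


@pytest.fixture(scope="session")
def quick_settings():
    """A short chain schedule for unit tests (ESS auto-extension off)."""
    return MCMCSettings(n_iter=2000, burn_in=500, thin=2, n_chains=1, min_ess=0.0)


@pytest.fixture(scope="session")
def prior():
    return PriorSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
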