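import numpy as np
import pytest
from hypothesis import settings

from chromaccess.simulate import SimConfig, generate_genome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully specified simulation for unit tests."""
    return SimConfig(
        genome_length=400_000,
        n_sites_per_class=8,
        mnase_depth=20_000,
        chip_depth=20_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
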