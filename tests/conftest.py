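import numpy as np
import pytest

from caprilact.simulate import SimConfig, simulate_herd


@pytest.fixture(scope="session")
def small_herd():
    """A 30-goat herd with the default haplotype inventory, fixed seed."""
    return simulate_herd(SimConfig(n_goats=30, n_haplotypes=8, seed=11))


@pytest.fixture(scope="session")
def study_herd():
    """A herd at the default (study-sized) configuration, fixed seed."""
    return simulate_herd(SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
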