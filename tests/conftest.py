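import pytest

from wrkyevo.scan import default_profile
from wrkyevo.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(n_families=20, seed=11))
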