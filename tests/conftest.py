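import numpy as np
import pytest

from fmisim.synthetic_data import calibrate_size_distribution, generate_population


@pytest.fixture(scope="session")
def size_dist():
    """The default moment-calibrated practice-size distribution."""
    return calibrate_size_distribution()


@pytest.fixture(scope="session")
def small_population(size_dist):
    """A 400-row synthetic physician table for structural tests."""
    return generate_population(400, seed=11, dist=size_dist)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
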