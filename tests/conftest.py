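import numpy as np
import pytest

from polsing import AnisotropyMap


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_map(rng):
    """Factory for random anisotropy maps with uniform (rho, delta)."""

    def make(shape=(16, 16), delta_range=(0.0, 2.0 * np.pi)):
        return AnisotropyMap(
            rho=rng.uniform(0.0, np.pi, shape),
            delta=rng.uniform(delta_range[0], delta_range[1], shape),
        )

    return make
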