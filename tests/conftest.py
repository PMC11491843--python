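import numpy as np
import pytest

from nfsim.phantom import PhantomSpec


@pytest.fixture
def small_spec():
    """Noise-free small phantom used by exactness checks."""
    return PhantomSpec(
        grid_dims=(12, 12, 6),
        noise_sd=0.0,
        drift_slope=0.0,
    )


@pytest.fixture
def noisy_spec():
    return PhantomSpec(grid_dims=(12, 12, 6), noise_sd=1.0, drift_slope=0.002)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
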