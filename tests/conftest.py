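import numpy as np
import pytest

from gliovol import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


SMALL_PHANTOM = dict(
    shape=(32, 32, 32),
    core_semiaxes=(4.0, 5.0, 3.5),
    bulk_semiaxes=(6.5, 7.5, 5.5),
    total_semiaxes=(10.0, 11.0, 8.0),
)


@pytest.fixture
def noiseless_phantom():
    """Small nested-ellipsoid phantom with no intensity noise."""
    return generate_phantom(PhantomSpec(**SMALL_PHANTOM, seed=7))


@pytest.fixture
def noisy_phantom():
    """Same geometry with noise at 10% of the 120-unit class separation."""
    return generate_phantom(
        PhantomSpec(**SMALL_PHANTOM, noise_sd_t1c=12.0, noise_sd_flair=12.0, seed=7)
    )
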