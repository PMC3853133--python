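import numpy as np
import pytest

from limbcast.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def spec96():
    """Full-resolution phantom spec (96³ @ 0.6 mm)."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom96(spec96):
    """Noiseless default phantom: (volume, ground truth)."""
    return generate_phantom(spec96)


@pytest.fixture(scope="session")
def spec64():
    """Coarse phantom spec (64³ @ 0.9 mm, same physical geometry) for
    cheaper Monte-Carlo style tests."""
    return PhantomSpec(grid_shape=(64, 64, 64), spacing_mm=0.9)


@pytest.fixture(scope="session")
def phantom64(spec64):
    return generate_phantom(spec64)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
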