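import numpy as np
import pytest

from canalseg.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Reduced phantom geometry for CPU tests."""
    return PhantomSpec(volume_shape=(48, 96, 96), bilateral=False, seed=0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
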