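import numpy as np
import pytest

from bravenet.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """A desk-scale phantom spec used by fast unit tests."""
    return PhantomSpec(shape=(48, 48, 16), n_trees=2)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """One small phantom pair (volume, labels), fixed seed."""
    return generate_phantom(small_spec, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
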