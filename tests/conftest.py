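import numpy as np
import pytest

from musclereg.phantom import PhantomSpec, make_limb_phantom
from musclereg.volumes_io import GreyVolume


@pytest.fixture(scope="session")
def small_phantom():
    """A quick 48x48x16 phantom with its ground-truth labels."""
    return make_limb_phantom(PhantomSpec(shape=(48, 48, 16), body_radius_mm=20.0, seed=3))


@pytest.fixture(scope="session")
def flat_phantom_spec():
    """Spec for slim phantoms used where many are generated."""
    return PhantomSpec(shape=(64, 64, 12), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_grey(rng, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return GreyVolume(rng.uniform(0, 100, size=shape), spacing, origin)
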