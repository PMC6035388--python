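import numpy as np
import pytest

from nucflux.geometry import GeometrySpec, make_geometry


@pytest.fixture(scope="session")
def flip_geometry():
    """Default fibroblast-like geometry with a nuclear 8x8 bleach square."""
    return make_geometry(GeometrySpec(), seed=1)


@pytest.fixture(scope="session")
def frap_geometry():
    from nucflux.datatypes import FRAP_PIXEL_SIZE
    return make_geometry(
        GeometrySpec(pixel_size=FRAP_PIXEL_SIZE, bleach_shape="circle",
                     bleach_size=11, nuclear_area=120.0, n_nucleoli=2),
        seed=4)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
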