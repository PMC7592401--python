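import numpy as np
import pytest

from dectmmd.materials import Material, MaterialLibrary, default_library


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def abdomen_lib():
    return default_library().subset(["air", "blood", "fat", "bone"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def unit_triangle_materials():
    """Vertices at (0,0), (1,0), (0,1) in (mu_low, mu_high) space."""
    return (
        Material("a", 1.0, 0.0, 0.0),
        Material("b", 1.0, 1.0, 0.0),
        Material("c", 1.0, 0.0, 1.0),
    )
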