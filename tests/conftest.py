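import numpy as np
import pytest

from unravel import generate_phantom
from unravel.geometry import VoxelGrid


@pytest.fixture(scope="session")
def bundle():
    """Default noise-free crossing-tract phantom, shared across tests."""
    return generate_phantom()


@pytest.fixture(scope="session")
def grid(bundle):
    ff = bundle.fixel_field
    return VoxelGrid(ff.shape, ff.affine)


def random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
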