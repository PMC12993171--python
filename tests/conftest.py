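import numpy as np
import pytest

from pezmap import PhantomSpec, generate_case
from pezmap.volumes import BINARY_MASK, VoxelGrid


@pytest.fixture(scope="session")
def spec48():
    return PhantomSpec.scaled((48, 48, 48))


@pytest.fixture(scope="session")
def noise_free_case48(spec48):
    """A deterministic noise-free desk-scale phantom, shared across tests."""
    return generate_case(spec48.noise_free(), seed=3)


@pytest.fixture(scope="session")
def noisy_case48(spec48):
    return generate_case(spec48, seed=11)


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(data).astype(np.uint8), spacing_mm=spacing,
                     kind=BINARY_MASK)


@pytest.fixture
def sphere_mask():
    def _build(shape, center, radius):
        idx = np.indices(shape)
        r2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
        return make_mask(r2 <= radius ** 2)
    return _build
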