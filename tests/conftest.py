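import numpy as np
import pytest

from nichedose import VolumeGrid, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """Shared default brain phantom (deterministic)."""
    return generate_phantom()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def make_grid(values, voxel_mm=2.0, origin=(0.0, 0.0, 0.0), unit=""):
    """Small helper: grid with an isotropic diagonal affine."""
    values = np.asarray(values)
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_mm
    aff[:3, 3] = origin
    return VolumeGrid(values, aff, unit=unit)
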