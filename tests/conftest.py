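import numpy as np
import pytest

from tibiaseg.volume_io import BinaryMask, ScanVolume, VolumeGeometry

REFERENCE_SPACING = (0.09, 0.075, 0.094)


@pytest.fixture
def small_geometry() -> VolumeGeometry:
    return VolumeGeometry(dims=(8, 6, 10), spacing=REFERENCE_SPACING)


@pytest.fixture
def cube_geometry() -> VolumeGeometry:
    return VolumeGeometry(dims=(3, 3, 3), spacing=REFERENCE_SPACING)


def make_mask(geometry: VolumeGeometry, coords) -> BinaryMask:
    """Binary mask with the given voxel coordinates set."""
    arr = np.zeros(geometry.dims, dtype=np.uint8)
    for c in coords:
        arr[tuple(c)] = 1
    return BinaryMask(geometry=geometry, labels=arr)


def random_mask(geometry: VolumeGeometry, rng, p: float = 0.4) -> BinaryMask:
    arr = (rng.random(geometry.dims) < p).astype(np.uint8)
    return BinaryMask(geometry=geometry, labels=arr)


@pytest.fixture
def make_scan():
    def _make(geometry: VolumeGeometry, seed: int = 0) -> ScanVolume:
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 2**14, size=geometry.dims).astype(np.uint16)
        return ScanVolume(geometry=geometry, intensities=arr)

    return _make
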