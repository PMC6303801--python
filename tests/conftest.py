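import numpy as np
import pytest

from gradmech.geometry import PixelGrid, VesselGeometry


@pytest.fixture
def grid8() -> PixelGrid:
    return PixelGrid(8, 8, 1.0)


@pytest.fixture
def grid16() -> PixelGrid:
    return PixelGrid(16, 16, 1.0)


@pytest.fixture
def centre_vessel(grid8) -> VesselGeometry:
    """Single 2x2 vessel block in the middle of an 8x8 grid."""
    mask = np.zeros(grid8.shape, dtype=np.uint8)
    mask[3:5, 3:5] = 1
    return VesselGeometry(grid8, [mask])


@pytest.fixture
def two_vessels(grid16) -> VesselGeometry:
    m1 = np.zeros(grid16.shape, dtype=np.uint8)
    m1[2:5, 2:5] = 1
    m2 = np.zeros(grid16.shape, dtype=np.uint8)
    m2[10:14, 9:12] = 1
    return VesselGeometry(grid16, [m1, m2])


def brute_force_distance(grid: PixelGrid, union_mask: np.ndarray) -> np.ndarray:
    """O(n^2) nearest-vessel-pixel search between pixel centres, in um."""
    rows, cols = np.nonzero(union_mask)
    out = np.empty(grid.shape)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            d2 = (rows - r) ** 2 + (cols - c) ** 2
            out[r, c] = np.sqrt(d2.min()) * grid.pixel_size
    return out
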