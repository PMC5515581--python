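import numpy as np
import pytest

import spherulescope as s

# A reduced crown that fits a 32-voxel box: used by tests that exercise the
# alignment machinery, where the full 48-voxel box would be needlessly slow.
SMALL_CROWN = s.CrownSpec(
    turret_diameter_nm=10.0,
    turret_height_nm=10.0,
    channel_diameter_nm=6.0,
    teeth_count=6,
    teeth_ring_diameter_nm=21.0,
)


def correlation(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


@pytest.fixture(scope="session")
def crown_map():
    """Default clean C12 crown on a membrane, 48^3 at 1 nm voxels."""
    return s.make_crown_density()


@pytest.fixture(scope="session")
def small_crown():
    """Reduced C6 crown in a 32^3 box for fast alignment tests."""
    return s.make_crown_density(SMALL_CROWN, box_edge_vox=32)


@pytest.fixture(scope="session")
def blob_volume():
    """An asymmetric (C1) three-blob object: no orientation ambiguity."""
    n = 32
    ax = np.arange(n) - (n - 1) / 2.0
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    data = np.zeros((n, n, n), dtype=np.float32)
    for (cz, cy, cx), sig, amp in [
        ((0, 0, 0), 3.0, 1.0),
        ((5, 3, -4), 2.0, 0.8),
        ((-4, 6, 2), 1.5, 0.6),
    ]:
        data += amp * np.exp(-((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2) / (2 * sig**2))
    return s.DensityVolume(data, 1.0)


@pytest.fixture(scope="session")
def spherule_phantom():
    """One spherule phantom (r = 22 nm) with ground truth, shared across tests."""
    return s.make_spherule_phantom(s.SpheruleSpec(radius_nm=22.0), seed=11)
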