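import numpy as np
import pytest

from mseeg.montage import Montage, geodesic_montage


@pytest.fixture(scope="session")
def geodesic():
    return geodesic_montage()


@pytest.fixture(scope="session")
def toy_pair_montage():
    """Two mirrored channels plus one midline channel, one ROI."""
    coords = np.array([
        [-0.6, 0.5, 0.62],   # L1
        [0.6, 0.5, 0.62],    # R1
        [0.0, 0.0, 1.0],     # Mz
    ])
    coords = coords / np.linalg.norm(coords, axis=1)[:, None]
    return Montage(["L1", "R1", "Mz"], coords,
                   rois={"F": ("L1", "R1", "Mz")},
                   pairs=[("L1", "R1")], midline=["Mz"])


@pytest.fixture(scope="session")
def toy16_montage():
    """16 roughly uniform unit-sphere electrodes (upper hemisphere)."""
    rng = np.random.default_rng(42)
    pts = rng.standard_normal((16, 3))
    pts[:, 2] = np.abs(pts[:, 2]) + 0.3
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    return Montage([f"T{i}" for i in range(16)], pts)


def symmetric_montage(n_per_side=14, n_mid=4, seed=3):
    """Mirror-symmetric synthetic montage (for flip/CSD equivariance tests)."""
    rng = np.random.default_rng(seed)
    left = rng.standard_normal((n_per_side, 3))
    left[:, 0] = -np.abs(left[:, 0]) - 0.3
    left[:, 2] = np.abs(left[:, 2])
    left /= np.linalg.norm(left, axis=1)[:, None]
    right = left * np.array([-1.0, 1.0, 1.0])
    mid = rng.standard_normal((n_mid, 3))
    mid[:, 0] = 0.0
    mid[:, 2] = np.abs(mid[:, 2]) + 0.5
    mid /= np.linalg.norm(mid, axis=1)[:, None]
    names = ([f"L{i}" for i in range(n_per_side)]
             + [f"R{i}" for i in range(n_per_side)]
             + [f"M{i}" for i in range(n_mid)])
    coords = np.vstack([left, right, mid])
    pairs = [(f"L{i}", f"R{i}") for i in range(n_per_side)]
    return Montage(names, coords, pairs=pairs,
                   midline=[f"M{i}" for i in range(n_mid)])


@pytest.fixture(scope="session")
def mirror_montage():
    return symmetric_montage()
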