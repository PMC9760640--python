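import numpy as np
import pytest

from biofilm3d.sim import SimCellState, grow_colony, voxelize


@pytest.fixture(scope="session")
def two_spheres():
    """Two well-separated digital spheres (radius 8) in one volume."""
    shape = (32, 32, 48)
    z, y, x = np.indices(shape)
    labels = np.zeros(shape, np.int32)
    labels[(z - 16) ** 2 + (y - 16) ** 2 + (x - 15) ** 2 <= 64] = 1
    labels[(z - 16) ** 2 + (y - 16) ** 2 + (x - 31) ** 2 <= 64] = 2
    return labels


@pytest.fixture(scope="session")
def touching_rods():
    """Two parallel rod-shaped cells in side-by-side contact."""
    c1 = SimCellState(1, None, [1.6, 1.6, 2.5], [0, 0, 1], 3.0, 1.0, 0.1)
    c2 = SimCellState(2, None, [1.6, 2.62, 2.5], [0, 0, 1], 3.0, 1.0, 0.1)
    return voxelize([c1, c2], (32, 44, 50))


@pytest.fixture(scope="session")
def small_colony_frames():
    """A slowly growing colony with a few divisions (for tracking tests)."""
    return grow_colony(30, d=1.0, l_div=3.0, n_seed_cells=4, rng_seed=7,
                       growth_rate=0.15)


@pytest.fixture(scope="session")
def random_blob_labels():
    """Random multi-blob label volumes for EDT oracle comparisons."""
    rng = np.random.default_rng(11)
    volumes = []
    for _ in range(10):
        shape = tuple(rng.integers(10, 33, size=3))
        labels = np.zeros(shape, np.int32)
        for k in (1, 2):
            center = rng.uniform(4, np.subtract(shape, 4))
            radius = rng.uniform(2, 5)
            zz, yy, xx = np.indices(shape)
            blob = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                    + (xx - center[2]) ** 2) <= radius**2
            labels[blob & (labels == 0)] = k
        volumes.append(labels)
    return volumes


def brute_force_cell_edt(labels: np.ndarray) -> np.ndarray:
    """O(n²) oracle: per in-cell voxel, min centre distance to any voxel of a
    different label (including background)."""
    from scipy.spatial.distance import cdist

    out = np.zeros(labels.shape, float)
    coords = np.indices(labels.shape).reshape(3, -1).T.astype(float)
    flat = labels.ravel()
    for k in np.unique(flat[flat > 0]):
        own = coords[flat == k]
        other = coords[flat != k]
        dist = np.empty(len(own))
        for i in range(0, len(own), 128):  # chunked to bound memory
            dist[i : i + 128] = cdist(own[i : i + 128], other).min(axis=1)
        out[tuple(own.T.astype(int))] = dist
    return out
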