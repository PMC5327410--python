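import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def paint_ellipsoid(data, center, semi_axes, value):
    """Reference voxelizer: set voxels with sum((x-c)/a)^2 <= 1."""
    grids = np.ogrid[tuple(slice(0, s) for s in data.shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    data[q <= 1.0] = value
    return data


@pytest.fixture
def solid_ellipsoid_volume():
    """Solid ellipsoid (semi-axes 40, 30, 30 voxels) in a 96³ grid."""
    from charvoid import Volume

    data = np.zeros((96, 96, 96), dtype=np.float32)
    paint_ellipsoid(data, (47.5, 47.5, 47.5), (40, 30, 30), 1.0)
    return Volume(data, voxel_size=50.0)


@pytest.fixture
def spheroid_seed_volume():
    """Ellipsoid seed containing 12 disjoint interior spheroids (r >= 3).

    Returns (Volume, list of (center, semi_axes)) ground truth.
    """
    from charvoid import Volume

    data = np.zeros((72, 72, 96), dtype=np.float32)
    center = (35.5, 35.5, 47.5)
    seed_axes = (30, 30, 42)
    paint_ellipsoid(data, center, seed_axes, 1.0)
    voids = []
    rng = np.random.default_rng(42)
    # 12 spheroids on a deterministic lattice, jittered, well separated
    offsets = [(dz, dy, dx)
               for dz in (-14, 0, 14) for dy in (-12, 12) for dx in (-24, 24)]
    for dz, dy, dx in offsets:
        c = (center[0] + dz, center[1] + dy, center[2] + dx)
        axes = tuple(rng.uniform(3.0, 4.5, size=3))
        paint_ellipsoid(data, c, axes, 0.0)
        voids.append((c, axes))
    assert len(voids) == 12
    return Volume(data, voxel_size=50.0), voids


def flood_fill_labels(mask, connectivity=6):
    """Independent brute-force BFS connected-component labelling."""
    from collections import deque

    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    if connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                 (0, 0, 1), (0, 0, -1)]
    else:
        neigh = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
                 for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        q = deque([start])
        labels[start] = current
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in neigh:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= pi < si for pi, si in zip(p, mask.shape)):
                    if mask[p] and not labels[p]:
                        labels[p] = current
                        q.append(p)
    return labels, current
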