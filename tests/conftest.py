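import numpy as np
import pytest

from vesseltopo import synthetic as syn
from vesseltopo.network import build_network
from vesseltopo.skeleton import VoxelSkeleton


@pytest.fixture
def y_skeleton():
    """Voxel 'Y': three straight 5-voxel arms meeting at one voxel."""
    center = (5, 5, 5)
    vox = {center}
    for dz, dy, dx in [(0, 0, 1), (0, 1, 0), (0, -1, -1)]:
        for k in range(1, 6):
            vox.add((center[0] + dz * k, center[1] + dy * k,
                     center[2] + dx * k))
    vox = np.array(sorted(vox))
    return VoxelSkeleton(shape=(12, 12, 12), voxels=vox,
                         spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def ring_skeleton():
    """A 12-voxel rectangular ring, all voxels of degree 2."""
    cells = [(1, 1), (1, 2), (1, 3), (1, 4), (2, 4), (3, 4),
             (3, 3), (3, 2), (3, 1), (2, 1)]
    vox = np.array(sorted((1, y, x) for y, x in cells))
    return VoxelSkeleton(shape=(3, 6, 6), voxels=vox, spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def path_network():
    """Straight segment of 10 unit-spaced nodes (total length 9)."""
    pos = {i: (float(i), 0.0, 0.0) for i in range(10)}
    return build_network(pos, [(i, i + 1) for i in range(9)])


@pytest.fixture
def grid_network():
    net, truth = syn.make_grid(3, 3, spacing=10.0)
    return net, truth


@pytest.fixture
def tree_network():
    net, truth = syn.make_tree(depth=2, branching=3, segment_length=30.0)
    return net, truth
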