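import numpy as np
import pytest

from cellgraphs import PointCloud, VolumeSpec, build_cell_graph


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_volume():
    """A 60 x 60 x 30 um test volume with 1 um isotropic voxels."""
    return VolumeSpec(extent_x=60, extent_y=60, extent_z=30, voxel_size=(1.0, 1.0, 1.0))


def random_geometric_graph(rng, n=None, box=100.0, threshold=None):
    """Random cloud in a cube with a threshold that gives sparse-to-dense
    graphs; returns the built CellGraph."""
    n = n if n is not None else int(rng.integers(2, 41))
    threshold = threshold if threshold is not None else float(rng.uniform(15, 60))
    coords = rng.uniform(0, box, size=(n, 3))
    return build_cell_graph(PointCloud(coords), threshold_um=threshold)


@pytest.fixture()
def geometric_graph_factory(rng):
    return lambda **kw: random_geometric_graph(rng, **kw)
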