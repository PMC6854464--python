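import numpy as np
import pytest

from swayrecon.camera import CameraIntrinsics
from swayrecon.graphs import DeformationGraph, build_graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_intr():
    return CameraIntrinsics(fx=500.0, fy=500.0, cx=320.0, cy=240.0,
                            width=640, height=480)


def make_plane_graph(n=12, spacing=0.01, z=0.0, jitter=0.0, seed=0):
    """Regular planar node grid triangulated into a deformation graph."""
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing,
                         indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel(), np.full(n * n, z)])
    if jitter:
        pts += rng.normal(0, jitter, pts.shape)
    normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return build_graph(pts, normals, cell=spacing * 0.9, radius=spacing * 2.5,
                       mode="plane")


@pytest.fixture
def plane_graph():
    return make_plane_graph()


def random_small_mesh(rng, n_pts=30):
    """Random bumpy height-field mesh for correspondence oracle tests."""
    pts = rng.uniform(-0.1, 0.1, (n_pts, 2))
    z = 0.03 * np.sin(20 * pts[:, 0]) * np.cos(15 * pts[:, 1])
    verts = np.column_stack([pts, z])
    from scipy.spatial import Delaunay

    faces = Delaunay(pts).simplices.astype(np.int64)
    normals = np.tile([0.0, 0.0, 1.0], (len(verts), 1))
    return DeformationGraph(nodes=verts, node_normals=normals, faces=faces)
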