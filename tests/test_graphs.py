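"""Normal estimation, voxel downsampling, triangulation and pruning."""

import numpy as np
import pytest

from swayrecon.camera import CameraIntrinsics
from swayrecon.graphs import (
    border_edges,
    build_graph,
    estimate_normals,
    faces_to_edges,
    prune_components,
    triangulate,
    voxel_downsample,
)
from swayrecon.preprocess import RGBDFrame, backproject


@pytest.fixture
def small_intr():
    return CameraIntrinsics(fx=100.0, fy=100.0, cx=16.0, cy=16.0,
                            width=32, height=32)


def _frame_cloud(depth, intr):
    frame = RGBDFrame(depth=depth, color=None)
    return frame, backproject(frame, intr)


class TestEstimateNormals:
    def test_frontoparallel_plane_normals_face_camera(self, small_intr):
        frame, cloud = _frame_cloud(np.ones((32, 32)), small_intr)
        out = estimate_normals(frame, small_intr, cloud)
        np.testing.assert_allclose(out.normals, [[0, 0, -1.0]] * len(out),
                                   atol=1e-9)

    def test_tilted_plane_matches_analytic_normal(self, small_intr):
        # plane z = 1 + y (45 degrees about the x-axis): z(v) solves
        # z = 1 + (v - cy)/fy * z  =>  z = 1 / (1 - (v - cy)/fy)
        v = np.arange(32, dtype=float)
        zrow = 1.0 / (1.0 - (v - small_intr.cy) / small_intr.fy)
        depth = np.tile(zrow[:, None], (1, 32))
        frame, cloud = _frame_cloud(depth, small_intr)
        out = estimate_normals(frame, small_intr, cloud)
        expected = np.array([0.0, -1.0, 1.0]) / np.sqrt(2)
        # camera-facing sign: dot(point, normal) < 0
        assert (np.einsum("ij,ij->i", out.points, out.normals) < 0).all()
        dots = np.abs(out.normals @ expected)
        assert np.quantile(dots, 0.05) > 1 - 1e-6

    def test_isolated_pixel_dropped(self, small_intr):
        depth = np.zeros((32, 32))
        depth[16, 16] = 1.0
        frame, cloud = _frame_cloud(depth, small_intr)
        with pytest.raises(ValueError):
            estimate_normals(frame, small_intr, cloud)


class TestVoxelDownsample:
    def test_single_cell_centroid(self, rng):
        pts = rng.uniform(0, 0.004, (20, 3))
        out = voxel_downsample(pts, cell=0.006)
        assert out.shape == (1, 3)
        np.testing.assert_allclose(out[0], pts.mean(axis=0), atol=1e-12)

    def test_far_points_stay_separate(self):
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        out = voxel_downsample(pts, cell=0.006)
        assert len(out) == 2

    def test_regular_grid_occupied_cell_count(self):
        # 12x12 points at 1 mm pitch span 11 mm -> 2x2 occupied 6 mm cells
        xs, ys = np.meshgrid(np.arange(12) * 0.001, np.arange(12) * 0.001)
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(144)])
        out = voxel_downsample(pts + 1e-9, cell=0.006)
        assert len(out) == 4

    def test_cell_key_uniqueness(self, rng):
        pts = rng.uniform(-0.1, 0.1, (500, 3))
        out = voxel_downsample(pts, cell=0.006)
        keys = np.floor(out / 0.006).astype(int)
        assert len(np.unique(keys, axis=0)) == len(out)

    def test_normals_renormalized(self, rng):
        pts = rng.uniform(0, 0.005, (10, 3))
        normals = np.tile([0.6, 0.8, 0.0], (10, 1))
        _, nrm = voxel_downsample(pts, cell=0.006, normals=normals)
        np.testing.assert_allclose(np.linalg.norm(nrm, axis=1), 1.0, atol=1e-12)


class TestTriangulate:
    def test_edge_length_bound(self, rng):
        pts = rng.uniform(0, 0.1, (80, 2))
        nodes = np.column_stack([pts, np.zeros(80)])
        faces = triangulate(nodes, radius=0.025, mode="plane")
        for f in faces:
            a, b, c = nodes[f]
            assert max(np.linalg.norm(a - b), np.linalg.norm(b - c),
                       np.linalg.norm(c - a)) <= 0.025

    def test_too_few_nodes_raises(self):
        with pytest.raises(ValueError):
            triangulate(np.zeros((2, 3)))

    def test_cylindrical_patch_is_meshable(self):
        theta = np.linspace(0, np.pi, 40)
        z = np.linspace(0, 0.2, 15)
        TH, ZZ = np.meshgrid(theta, z)
        nodes = np.column_stack(
            [0.1 * np.cos(TH).ravel(), 0.1 * np.sin(TH).ravel(), ZZ.ravel()]
        )
        faces = triangulate(nodes, radius=0.05)
        assert len(faces) > 0
        assert set(np.unique(faces)) <= set(range(len(nodes)))


class TestPruneComponents:
    def _two_components(self, n1, n2):
        g1 = np.column_stack([np.arange(n1) * 0.01, np.zeros(n1), np.zeros(n1)])
        g2 = np.column_stack([np.arange(n2) * 0.01, np.full(n2, 5.0), np.zeros(n2)])
        nodes = np.vstack([g1, [0.005, 0.01, 0], g2, [0.005, 5.01, 0]])
        # chain of triangles within each component
        f1 = [[i, i + 1, n1] for i in range(n1 - 1)]
        off = n1 + 1
        f2 = [[off + i, off + i + 1, off + n2] for i in range(n2 - 1)]
        return nodes, np.array(f1 + f2, dtype=np.int64)

    def test_single_component_unchanged(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        faces = np.array([[0, 1, 2]])
        out_nodes, out_faces = prune_components(nodes, faces)
        assert len(out_nodes) == 3 and len(out_faces) == 1

    def test_larger_component_kept(self):
        nodes, faces = self._two_components(100, 5)
        out_nodes, _ = prune_components(nodes, faces)
        assert len(out_nodes) == 101  # 100 chain nodes + shared apex

    def test_tie_break_lowest_index(self):
        nodes, faces = self._two_components(5, 5)
        out_nodes, _ = prune_components(nodes, faces)
        # first component contains node 0
        np.testing.assert_allclose(out_nodes[0], nodes[0])

    def test_pruned_graph_fully_reachable(self, rng):
        g = build_graph(
            np.column_stack([rng.uniform(0, 0.1, (300, 2)), np.zeros(300)]),
            np.tile([0.0, 0.0, 1.0], (300, 1)),
            cell=0.006, radius=0.025, mode="plane",
        )
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import breadth_first_order

        adj = coo_matrix(
            (np.ones(len(g.edges)), (g.edges[:, 0], g.edges[:, 1])),
            shape=(g.n_nodes, g.n_nodes),
        )
        order, _ = breadth_first_order(adj, 0, directed=False)
        assert len(order) == g.n_nodes


def test_border_edges_are_single_face_edges():
    #  two triangles sharing an edge: the shared edge is interior
    faces = np.array([[0, 1, 2], [1, 3, 2]])
    psi = border_edges(faces)
    assert [1, 2] not in psi.tolist()
    assert len(psi) == 4
    # every edge in psi has face count exactly 1
    all_edges = faces_to_edges(faces)
    assert len(all_edges) == 5
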