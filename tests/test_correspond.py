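"""Exact point-triangle / point-mesh closest points and rejection rules."""

import numpy as np
import pytest

from swayrecon.correspond import (
    REGION_EDGE,
    REGION_FACE,
    REGION_VERTEX,
    MeshDistanceQuery,
    closest_point_correspondences,
    closest_point_on_triangles,
    point_triangle_closest,
    reject,
    shortest_distance_correspondences,
)
from tests.conftest import random_small_mesh


def brute_force_closest(p, tri, n_grid=400):
    """Dense barycentric sampling oracle for the closest point on a triangle."""
    u = np.linspace(0, 1, n_grid)
    uu, vv = np.meshgrid(u, u)
    keep = uu + vv <= 1.0
    uu, vv = uu[keep], vv[keep]
    pts = (
        np.outer(1 - uu - vv, tri[0]) + np.outer(uu, tri[1]) + np.outer(vv, tri[2])
    )
    d = np.linalg.norm(pts - p, axis=1)
    return pts[np.argmin(d)], d.min()


TRI = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


class TestPointTriangleClosest:
    def test_orthogonal_projection_onto_face(self):
        centroid = TRI.mean(axis=0)
        q, region = point_triangle_closest(centroid + [0, 0, 1], *TRI)
        np.testing.assert_allclose(q, centroid, atol=1e-12)
        assert region == "face"

    def test_vertex_region(self):
        q, region = point_triangle_closest((2.0, -1.0, 0.0), *TRI)
        np.testing.assert_allclose(q, [1, 0, 0], atol=1e-12)
        assert region.startswith("vertex")
        bq, _ = brute_force_closest(np.array([2.0, -1.0, 0.0]), TRI)
        np.testing.assert_allclose(q, bq, atol=1e-2)

    def test_point_inside_triangle_is_fixed(self):
        p = np.array([0.2, 0.3, 0.0])
        q, region = point_triangle_closest(p, *TRI)
        np.testing.assert_allclose(q, p, atol=1e-12)
        assert region == "face"

    def test_degenerate_triangle_raises(self):
        with pytest.raises(ValueError):
            point_triangle_closest((0, 0, 1), (0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_matches_dense_sampling_oracle(self, rng):
        for _ in range(30):
            tri = rng.normal(0, 1, (3, 3))
            if np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0])) < 1e-3:
                continue
            p = rng.normal(0, 2, 3)
            q, _ = point_triangle_closest(p, *tri)
            _, d_oracle = brute_force_closest(p, tri, n_grid=600)
            d = np.linalg.norm(q - p)
            assert d <= d_oracle + 1e-5  # oracle is a discretised upper bound

    def test_region_classification_consistent(self, rng):
        """Vectorised classification matches recomputed barycentric location."""
        tri = rng.normal(0, 1, (50, 3, 3))
        p = rng.normal(0, 2, (50, 3))
        closest, bary, region, _ = closest_point_on_triangles(p, tri)
        np.testing.assert_allclose(
            closest, np.einsum("nk,nkj->nj", bary, tri), atol=1e-9
        )
        on_vertex = np.isclose(bary, 1.0).any(axis=1)
        assert (region[on_vertex] != REGION_FACE).all()
        interior = (bary > 1e-9).all(axis=1)
        assert (region[interior] == REGION_FACE).all()


class TestMeshQuery:
    def test_matches_exhaustive_minimum(self, rng):
        graph = random_small_mesh(rng, n_pts=60)
        query = MeshDistanceQuery(graph.nodes, graph.faces)
        pts = rng.uniform(-0.15, 0.15, (200, 3))
        closest, dist, _, _, _, _ = query.query(pts)
        tri = graph.nodes[graph.faces]
        for i in range(len(pts)):
            cc, _, _, _ = closest_point_on_triangles(
                np.tile(pts[i], (len(tri), 1)), tri
            )
            d_all = np.linalg.norm(cc - pts[i], axis=1)
            assert abs(dist[i] - d_all.min()) < 1e-9

    def test_source_node_on_target_vertex(self, rng):
        graph = random_small_mesh(rng)
        query = MeshDistanceQuery(graph.nodes, graph.faces)
        closest, dist, _, _, _, _ = query.query(graph.nodes[:5])
        assert np.max(dist) < 1e-12
        np.testing.assert_allclose(closest, graph.nodes[:5], atol=1e-12)

    def test_hits_lie_on_surface(self, rng):
        graph = random_small_mesh(rng)
        query = MeshDistanceQuery(graph.nodes, graph.faces)
        pts = rng.uniform(-0.12, 0.12, (50, 3))
        closest, _, face, bary, _, _ = query.query(pts)
        recon = np.einsum("nk,nkj->nj", bary, graph.nodes[graph.faces[face]])
        np.testing.assert_allclose(closest, recon, atol=1e-9)

    def test_empty_target_raises(self):
        with pytest.raises(ValueError):
            MeshDistanceQuery(np.zeros((3, 3)), np.zeros((0, 3), dtype=int))


class TestCorrespondences:
    def test_shortest_never_farther_than_closest_vertex(self, rng):
        src = random_small_mesh(rng, n_pts=40)
        tgt = random_small_mesh(np.random.default_rng(99), n_pts=50)
        c_short = shortest_distance_correspondences(src, tgt)
        c_close = closest_point_correspondences(src, tgt)
        assert (c_short.distances <= c_close.distances + 1e-12).all()

    def test_rejection_rules(self, rng):
        tgt = random_small_mesh(rng, n_pts=40)
        src = random_small_mesh(rng, n_pts=10)
        corrs = shortest_distance_correspondences(src, tgt)
        sn = src.node_normals
        # distance rule: inflate one distance beyond 2 cm
        corrs.distances[0] = 0.03
        out = reject(corrs, tgt, sn)
        assert out.weights[0] == 0
        # normal rule: antiparallel normals at tiny distance
        corrs.distances[:] = 0.001
        out = reject(corrs, tgt, -corrs.target_normals)
        assert (out.weights == 0).all()

    def test_border_hits_rejected(self, rng):
        tgt = random_small_mesh(rng, n_pts=40)
        # probe points far outside the patch hit its border
        src_nodes = tgt.nodes.mean(axis=0) + np.array(
            [[0.5, 0.0, 0.0], [0.0, 0.5, 0.0], [-0.5, 0.0, 0.0]]
        )
        from swayrecon.graphs import DeformationGraph

        src = DeformationGraph(
            nodes=src_nodes,
            node_normals=np.tile([0.0, 0.0, 1.0], (3, 1)),
            faces=np.array([[0, 1, 2]]),
        )
        corrs = shortest_distance_correspondences(src, tgt)
        corrs.distances[:] = 0.001  # isolate the border criterion
        out = reject(corrs, tgt, np.tile([0.0, 0.0, 1.0], (3, 1)))
        assert (out.weights == 0).all()

    def test_reject_is_idempotent_and_monotone(self, rng):
        tgt = random_small_mesh(rng, n_pts=40)
        src = random_small_mesh(np.random.default_rng(5), n_pts=20)
        corrs = shortest_distance_correspondences(src, tgt)
        once = reject(corrs, tgt, src.node_normals)
        twice = reject(once, tgt, src.node_normals)
        assert (once.weights == twice.weights).all()
        assert (once.weights <= corrs.weights).all()
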