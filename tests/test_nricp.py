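"""Stacked-system assembly, closed-form solve and its limiting behaviours."""

import numpy as np
import pytest

from swayrecon.correspond import CorrespondenceSet, REGION_FACE
from swayrecon.graphs import DeformationGraph, apply_transforms, identity_transforms
from swayrecon.nricp import (
    assemble,
    incidence_matrix,
    pairwise_nricp,
    solve,
    system_cost,
)
from tests.conftest import make_plane_graph


def make_corrs(graph, targets, weights=None):
    J = graph.n_nodes
    return CorrespondenceSet(
        target_points=np.asarray(targets, dtype=float),
        target_normals=np.tile([0.0, 0.0, 1.0], (J, 1)),
        weights=np.ones(J) if weights is None else np.asarray(weights, float),
        distances=np.zeros(J),
        faces=np.zeros(J, dtype=np.int64),
        bary=np.tile([1.0, 0.0, 0.0], (J, 1)),
        region=np.full(J, REGION_FACE, dtype=np.int8),
        sub=np.full(J, -1, dtype=np.int8),
    )


class TestIncidenceMatrix:
    def test_single_edge(self):
        g = DeformationGraph(
            nodes=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]),
            node_normals=np.tile([0, 0, 1.0], (3, 1)),
            faces=np.array([[0, 1, 2]]),
        )
        M = incidence_matrix(g).toarray()
        # three edges, each row -1 at the lower and +1 at the higher index
        assert M.shape == (3, 3)
        assert (M.sum(axis=1) == 0).all()
        row01 = M[(M[:, 0] != 0) & (M[:, 1] != 0)][0]
        np.testing.assert_array_equal(row01, [-1, 1, 0])

    def test_path_graph_rank(self):
        # path of J nodes has J-1 edges and incidence rank J-1
        J = 7
        nodes = np.column_stack([np.arange(J, dtype=float), np.zeros(J), np.zeros(J)])
        apex = np.array([[3.0, 1.0, 0.0]])
        g = DeformationGraph(
            nodes=np.vstack([nodes, apex]),
            node_normals=np.tile([0, 0, 1.0], (J + 1, 1)),
            faces=np.array([[i, i + 1, J] for i in range(J - 1)]),
        )
        M = incidence_matrix(g).toarray()
        # restrict to the path's edges only
        path_rows = M[(M[:, J] == 0)]
        assert path_rows.shape[0] == J - 1
        assert np.linalg.matrix_rank(path_rows) == J - 1


class TestSolveLimits:
    def test_perfect_affine_recovered(self, rng):
        """Correspondences generated by a known global affine are recovered
        per node in the vanishing-stiffness limit (a single data row per node
        cannot identify the affine alone; any positive stiffness selects the
        zero-residual constant-affine solution exactly)."""
        g = make_plane_graph(n=6, jitter=0.003)
        A = np.eye(3) + rng.normal(0, 0.1, (3, 3))
        t = rng.normal(0, 0.05, 3)
        targets = g.nodes @ A + t
        sys = assemble(g, make_corrs(g, targets), alpha=1e-3, beta=1.0)
        X = solve(sys)
        expected = np.concatenate([A, t[None]], axis=0)
        for Xi in X:
            np.testing.assert_allclose(Xi, expected, atol=1e-6)

    def test_zero_correspondences_give_identity(self):
        g = make_plane_graph(n=6, jitter=0.002)
        targets = np.zeros_like(g.nodes)
        sys = assemble(g, make_corrs(g, targets, weights=np.zeros(g.n_nodes)),
                       alpha=1.0, beta=1.0)
        X = solve(sys)
        np.testing.assert_allclose(X, identity_transforms(g.n_nodes), atol=1e-8)

    def test_high_stiffness_makes_field_constant(self, rng):
        g = make_plane_graph(n=6, jitter=0.002)
        targets = g.nodes + rng.normal(0, 0.01, g.nodes.shape)
        sys = assemble(g, make_corrs(g, targets), alpha=1e6, beta=1.0)
        X = solve(sys)
        spread = np.abs(X - X.mean(axis=0)).max()
        assert spread < 1e-4

    def test_solver_meets_gradient_tolerance(self, rng):
        g = make_plane_graph(n=8, jitter=0.002)
        targets = g.nodes + rng.normal(0, 0.005, g.nodes.shape)
        sys = assemble(g, make_corrs(g, targets), alpha=20.0, beta=1.0)
        X = solve(sys).reshape(-1, 3)
        AtA = sys.A.T @ sys.A
        AtB = sys.A.T @ sys.B
        grad = np.abs(AtA @ X - AtB).max()
        assert grad < 1e-8 * max(np.abs(AtB).max(), 1.0)

    def test_cost_non_increasing_for_fixed_correspondences(self, rng):
        g = make_plane_graph(n=8, jitter=0.002)
        targets = g.nodes + rng.normal(0, 0.01, g.nodes.shape)
        sys = assemble(g, make_corrs(g, targets), alpha=20.0, beta=1.0)
        before = system_cost(sys, g.X)["total"]
        X = solve(sys)
        after = system_cost(sys, X)["total"]
        assert after <= before + 1e-12


class TestPairwise:
    def test_identity_fixed_point(self):
        """Aligning a graph to an exact copy of itself yields identity."""
        g = make_plane_graph(n=8, jitter=0.002)
        tgt = make_plane_graph(n=8, jitter=0.002)
        X = pairwise_nricp(g, tgt, alpha=20.0, max_iters=10)
        np.testing.assert_allclose(X, identity_transforms(g.n_nodes), atol=1e-6)

    def test_recovers_out_of_plane_translation(self):
        """A normal-direction offset is fully observable to surface ICP
        (in-plane offsets of a featureless plane are not)."""
        src = make_plane_graph(n=8, jitter=0.002)
        tgt = make_plane_graph(n=8, jitter=0.002)
        tgt.nodes = tgt.nodes + np.array([0.0, 0.0, 0.004])
        X = pairwise_nricp(src, tgt, alpha=20.0, d_max=0.02)
        moved = apply_transforms(src.nodes, X)
        interior = ~src.border_vertex_set()
        err = np.abs(moved[:, 2] - (src.nodes[:, 2] + 0.004))
        assert np.median(err[interior]) < 1e-3

    def test_unknown_variant_raises(self):
        g = make_plane_graph(n=5)
        with pytest.raises(ValueError):
            pairwise_nricp(g, g, variant="projective")
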