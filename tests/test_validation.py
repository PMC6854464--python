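"""Landmark-spread error, geodesic contours, Coons patch and volumetry."""

import numpy as np
import pytest
import trimesh

from swayrecon.camera import CameraIntrinsics, RigidTransform
from swayrecon.validation import (
    assert_watertight,
    breast_volume,
    coons_patch,
    derive_breast_corners,
    geodesic_contour,
    landmark_error,
    landmark_position,
    mesh_volume,
    repeatability,
    segment_and_close,
    triangulate_grid,
)


class TestLandmarkError:
    def test_coincident_samples_zero_error(self):
        samples = {0: np.tile([1.0, 2.0, 3.0], (5, 1)),
                   1: np.tile([0.0, 0.5, 0.2], (3, 1))}
        assert landmark_error(samples) == pytest.approx(0.0, abs=1e-15)

    def test_two_sample_hand_computation(self):
        d = 0.004
        samples = {0: np.array([[0, 0, 0], [d, 0, 0.0]])}
        # sample covariance with divisor n-1: var = d^2/2 on one axis
        assert landmark_error(samples) == pytest.approx(d**2 / 2, rel=1e-12)

    def test_matches_brute_force_covariance(self, rng):
        samples = {i: rng.normal(0, 0.003, (rng.integers(2, 9), 3))
                   for i in range(6)}
        norms = []
        for pts in samples.values():
            n = len(pts)
            mu = pts.mean(axis=0)
            cov = sum(np.outer(p - mu, p - mu) for p in pts) / (n - 1)
            norms.append(np.sqrt((cov**2).sum()))
        assert landmark_error(samples) == pytest.approx(np.mean(norms), rel=1e-12)

    def test_invariant_under_global_rigid_transform(self, rng):
        from scipy.spatial.transform import Rotation

        samples = {i: rng.normal(0, 0.005, (6, 3)) for i in range(4)}
        R = Rotation.random(random_state=1).as_matrix()
        t = rng.normal(0, 1, 3)
        moved = {i: s @ R.T + t for i, s in samples.items()}
        assert landmark_error(moved) == pytest.approx(
            landmark_error(samples), abs=1e-10
        )

    def test_isotropic_noise_monte_carlo(self, rng):
        # eps_L for isotropic sigma^2 I covariance is sigma^2 sqrt(3)
        sigma = 0.002
        samples = {i: rng.normal(0, sigma, (400, 3)) for i in range(40)}
        got = landmark_error(samples)
        assert got == pytest.approx(sigma**2 * np.sqrt(3), rel=0.1)

    def test_single_sample_landmarks_excluded(self):
        samples = {0: np.zeros((1, 3)), 1: np.array([[0, 0, 0], [0.01, 0, 0]])}
        assert landmark_error(samples) > 0
        with pytest.raises(ValueError):
            landmark_error({0: np.zeros((1, 3))})


def test_landmark_position_backprojects_and_unposes():
    intr = CameraIntrinsics(fx=100, fy=100, cx=50, cy=50, width=100, height=100)
    # camera looking down +z shifted by t: world = cam - t for identity R
    pose = RigidTransform(np.eye(3), np.array([0.0, 0.0, -1.0]))
    pos = landmark_position((50.0, 50.0), 2.0, intr, pose, warp=None)
    np.testing.assert_allclose(pos, [0, 0, 3.0], atol=1e-12)
    with pytest.warns(UserWarning):
        assert landmark_position((50.0, 50.0), 0.0, intr, pose) is None


class TestGeodesicContour:
    def _grid_mesh(self, n=10, pitch=1.0):
        xs, ys = np.meshgrid(np.arange(n) * pitch, np.arange(n) * pitch)
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
        idx = np.arange(n * n).reshape(n, n)
        a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
        c, d = idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()
        faces = np.vstack([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
        return trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    def test_trivial_single_vertex_path(self):
        mesh = self._grid_mesh()
        assert geodesic_contour(mesh, 3, 3).tolist() == [3]

    def test_matches_networkx_dijkstra(self):
        import networkx as nx

        mesh = self._grid_mesh()
        G = nx.Graph()
        for (u, v), w in zip(mesh.edges_unique, mesh.edges_unique_length):
            G.add_edge(int(u), int(v), weight=float(w))
        path = geodesic_contour(mesh, 0, 99)
        length = sum(
            np.linalg.norm(mesh.vertices[a] - mesh.vertices[b])
            for a, b in zip(path[:-1], path[1:])
        )
        expected = nx.shortest_path_length(G, 0, 99, weight="weight")
        assert length == pytest.approx(expected, rel=1e-12)

    def test_disconnected_raises(self):
        mesh = trimesh.Trimesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                               [5, 5, 0], [6, 5, 0], [5, 6, 0.0]]),
            faces=np.array([[0, 1, 2], [3, 4, 5]]), process=False,
        )
        with pytest.raises(ValueError):
            geodesic_contour(mesh, 0, 3)


class TestCoonsPatch:
    def test_boundary_reproduction(self, rng):
        n = 9
        bottom = np.column_stack([np.linspace(0, 1, n), np.zeros(n),
                                  rng.normal(0, 0.05, n)])
        top = np.column_stack([np.linspace(0, 1, n), np.ones(n),
                               rng.normal(0, 0.05, n)])
        left = np.column_stack([np.zeros(n), np.linspace(0, 1, n),
                                np.linspace(bottom[0, 2], top[0, 2], n)])
        right = np.column_stack([np.ones(n), np.linspace(0, 1, n),
                                 np.linspace(bottom[-1, 2], top[-1, 2], n)])
        grid = coons_patch(bottom, top, left, right)
        np.testing.assert_allclose(grid[:, 0], bottom, atol=1e-12)
        np.testing.assert_allclose(grid[:, -1], top, atol=1e-12)
        np.testing.assert_allclose(grid[0, :], left, atol=1e-12)
        np.testing.assert_allclose(grid[-1, :], right, atol=1e-12)

    def test_planar_square_stays_planar_and_uniform(self):
        n = 11
        u = np.linspace(0, 1, n)
        bottom = np.column_stack([u, np.zeros(n), np.zeros(n)])
        top = np.column_stack([u, np.ones(n), np.zeros(n)])
        left = np.column_stack([np.zeros(n), u, np.zeros(n)])
        right = np.column_stack([np.ones(n), u, np.zeros(n)])
        grid = coons_patch(bottom, top, left, right)
        assert np.abs(grid[..., 2]).max() < 1e-14
        np.testing.assert_allclose(np.diff(grid[:, :, 0], axis=0), 0.1, atol=1e-12)

    def test_unequal_contours_resampled(self):
        bottom = np.array([[0, 0, 0], [1, 0, 0.0]])
        top = np.array([[0, 1, 0], [0.5, 1, 0], [1, 1, 0.0]])
        left = np.array([[0, 0, 0], [0, 1, 0.0]])
        right = np.array([[1, 0, 0], [1, 1, 0.0]])
        grid = coons_patch(bottom, top, left, right)
        assert grid.shape == (3, 2, 3)

    def test_mismatched_corners_raise(self):
        c = np.array([[0, 0, 0], [1, 0, 0.0]])
        with pytest.raises(ValueError):
            coons_patch(c, c + [0, 1, 0], c[:, [1, 0, 2]], c + [5, 0, 0])


class TestVolume:
    def test_unit_cube_exact(self):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        assert mesh_volume(cube) == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_within_half_percent(self):
        r = 0.0620
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=r)
        vol = abs(mesh_volume(sphere))
        assert abs(vol - 4 / 3 * np.pi * r**3) / (4 / 3 * np.pi * r**3) < 0.005

    def test_orientation_flips_sign_only(self):
        cube = trimesh.creation.box(extents=(1.0, 2.0, 0.5))
        flipped = trimesh.Trimesh(cube.vertices, cube.faces[:, ::-1], process=False)
        assert mesh_volume(flipped) == pytest.approx(-mesh_volume(cube), abs=1e-12)

    def test_matches_trimesh_mass_properties(self, rng):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=0.08)
        assert abs(mesh_volume(mesh)) == pytest.approx(mesh.volume, rel=1e-9)

    def test_watertight_audit(self):
        cube = trimesh.creation.box()
        assert_watertight(cube)
        open_mesh = trimesh.Trimesh(cube.vertices, cube.faces[:-1], process=False)
        with pytest.raises(ValueError):
            assert_watertight(open_mesh)


class TestRepeatability:
    def test_identical_pairs_give_zero(self):
        cr, cv = repeatability([[500, 500], [800, 800]])
        assert cr == 0 and cv == 0

    def test_hand_computed_example(self):
        cr, cv = repeatability([[1000, 1020], [500, 510]])
        sigma_w = np.sqrt((200 + 50) / 2)
        assert cr == pytest.approx(2.77 * sigma_w, rel=1e-12)
        assert cv == pytest.approx(100 * sigma_w / 757.5, rel=1e-12)

    def test_single_subject_two_point_variance(self):
        d = 30.0
        cr, _ = repeatability([[400, 400 + d]])
        assert cr == pytest.approx(2.77 * np.sqrt(d**2 / 2), rel=1e-12)


class TestBreastSegmentation:
    def test_hemisphere_bump_volume_recovered(self):
        """Hemispherical bump on a plane: segmented volume ~ 2/3 pi r^3."""
        r_b = 0.05
        n = 80
        xs, ys = np.meshgrid(np.linspace(-0.12, 0.12, n),
                             np.linspace(-0.12, 0.12, n))
        rr = np.hypot(xs, ys)
        zs = np.where(rr < r_b, np.sqrt(np.maximum(r_b**2 - rr**2, 0)), 0.0)
        verts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        idx = np.arange(n * n).reshape(n, n)
        a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
        c, d = idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()
        faces = np.vstack([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        corners = derive_breast_corners(
            mesh,
            sternum=(-0.09, 0.0, 0.0),
            fold=(0.09, -0.09, 0.0),
            axilla=(0.09, 0.09, 0.0),
            up=(0.0, 1.0, 0.0),
        )
        region = segment_and_close(mesh, corners, seed_point=(0, 0, r_b))
        expected = 2 / 3 * np.pi * r_b**3 * 1000.0  # litres
        assert region.volume_l == pytest.approx(expected, rel=0.10)

    def test_landmark_driven_region_matches_explicit_seed(self):
        r_b = 0.05
        n = 80
        xs, ys = np.meshgrid(np.linspace(-0.12, 0.12, n),
                             np.linspace(-0.12, 0.12, n))
        rr = np.hypot(xs, ys)
        zs = np.where(rr < r_b, np.sqrt(np.maximum(r_b**2 - rr**2, 0)), 0.0)
        verts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        idx = np.arange(n * n).reshape(n, n)
        a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
        c, d = idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()
        faces = np.vstack([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        from swayrecon.validation import breast_region_from_landmarks

        region = breast_region_from_landmarks(
            mesh, (-0.09, 0.0, 0.0), (0.09, -0.09, 0.0), (0.09, 0.09, 0.0),
            up=(0.0, 1.0, 0.0),
        )
        expected = 2 / 3 * np.pi * r_b**3 * 1000.0
        assert region.volume_l == pytest.approx(expected, rel=0.10)

    def test_closed_meshes_are_watertight(self):
        # reuse a coarse bump; watertightness is audited inside
        r_b = 0.04
        n = 40
        xs, ys = np.meshgrid(np.linspace(-0.1, 0.1, n), np.linspace(-0.1, 0.1, n))
        rr = np.hypot(xs, ys)
        zs = np.where(rr < r_b, np.sqrt(np.maximum(r_b**2 - rr**2, 0)), 0.0)
        verts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        idx = np.arange(n * n).reshape(n, n)
        a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
        c, d = idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()
        faces = np.vstack([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        corners = derive_breast_corners(mesh, (-0.08, 0, 0), (0.08, -0.08, 0),
                                        (0.08, 0.08, 0), up=(0, 1, 0))
        region = segment_and_close(mesh, corners, seed_point=(0, 0, r_b))
        assert_watertight(region.breast_closed)
        assert_watertight(region.wall_closed)
        assert breast_volume(region.breast_closed, region.wall_closed) > 0
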