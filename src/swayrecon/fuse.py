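"""Fuse warped per-frame clouds into one denoised, meshed, colored model.

Stages: concatenation of all warped full-resolution clouds; moving-least-
squares (MLS) smoothing with a degree-2 local polynomial; normal-orientation
consistency propagation; grid resampling to uniform 1 mm density; implicit
surface reconstruction from the oriented points (a signed moving-least-
squares distance field sampled on a uniform grid and polygonised with
marching cubes); clipping of excess surface far from the data; and vertexwise
colour reintegration with circular (shortest-arc) hue averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from numba import njit
from scipy import sparse
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree
from scipy.spatial import cKDTree
from skimage import measure
from skimage.color import hsv2rgb, rgb2hsv

from .graphs import voxel_downsample

__all__ = [
    "FusedCloud",
    "TorsoModel",
    "fuse_clouds",
    "mls_smooth",
    "reorient_normals",
    "grid_resample",
    "poisson_mesh",
    "implicit_surface",
    "clip_excess",
    "reintegrate_color",
    "sequential_hue_mean",
]


@dataclass
class FusedCloud:
    points: np.ndarray
    normals: np.ndarray | None = None
    colors: np.ndarray | None = None
    frame_ids: np.ndarray | None = None

    def __len__(self):
        return len(self.points)


@dataclass
class TorsoModel:
    """Final fused point set and cleaned colored triangle mesh."""

    points: FusedCloud
    mesh: trimesh.Trimesh  # clipped presentation mesh
    watertight_mesh: trimesh.Trimesh | None = None  # pre-clip implicit surface


def fuse_clouds(clouds) -> FusedCloud:
    """Concatenate warped clouds, preserving colour and frame provenance."""
    pts = np.vstack([c.points for c in clouds])
    normals = None
    if all(c.normals is not None for c in clouds):
        normals = np.vstack([c.normals for c in clouds])
    colors = None
    if all(c.colors is not None for c in clouds):
        colors = np.vstack([c.colors for c in clouds])
    frame_ids = np.concatenate(
        [np.full(len(c), getattr(c, "frame_index", i)) for i, c in enumerate(clouds)]
    )
    return FusedCloud(pts, normals, colors, frame_ids)


@njit(cache=True)
def _mls_kernel(pts, normals, nb_idx, nb_count, min_fit):  # pragma: no cover
    n = pts.shape[0]
    out_pts = pts.copy()
    out_nrm = normals.copy()
    fitted = np.zeros(n, dtype=np.bool_)
    for i in range(n):
        k = nb_count[i]
        if k < min_fit:
            continue
        nrm = normals[i]
        # local tangent frame
        a = np.array([1.0, 0.0, 0.0])
        if abs(nrm[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        t1 = np.cross(nrm, a)
        t1 = t1 / np.sqrt(t1[0] ** 2 + t1[1] ** 2 + t1[2] ** 2)
        t2 = np.cross(nrm, t1)
        AtA = np.zeros((6, 6))
        Atb = np.zeros(6)
        for jj in range(k):
            q = pts[nb_idx[i, jj]] - pts[i]
            x = q[0] * t1[0] + q[1] * t1[1] + q[2] * t1[2]
            y = q[0] * t2[0] + q[1] * t2[1] + q[2] * t2[2]
            z = q[0] * nrm[0] + q[1] * nrm[1] + q[2] * nrm[2]
            row = np.array([1.0, x, y, x * x, x * y, y * y])
            for r in range(6):
                Atb[r] += row[r] * z
                for cidx in range(6):
                    AtA[r, cidx] += row[r] * row[cidx]
        # ridge for stability of the 6x6 normal equations
        for r in range(6):
            AtA[r, r] += 1e-12
        coef = np.linalg.solve(AtA, Atb)
        out_pts[i] = pts[i] + coef[0] * nrm
        # surface normal of z = f(x,y) at the origin: (-fx, -fy, 1)
        g = -coef[1] * t1 - coef[2] * t2 + nrm
        gn = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
        g = g / gn
        if g[0] * nrm[0] + g[1] * nrm[1] + g[2] * nrm[2] < 0:
            g = -g
        out_nrm[i] = g
        fitted[i] = True
    return out_pts, out_nrm, fitted


def mls_smooth(
    points: np.ndarray,
    normals: np.ndarray,
    radius: float = 0.008,
    min_fit: int = 5,
    max_neighbors: int = 64,
):
    """Project each point onto a local degree-2 polynomial fit.

    The polynomial height field is fitted over the neighbours within
    ``radius`` (at most ``max_neighbors``, nearest first) in the tangent
    frame of the point's normal; the point moves along its normal onto the
    fitted surface and the normal is replaced by the fitted surface normal.
    Points with fewer than ``min_fit`` neighbours pass through unchanged.
    Returns (points, normals, fitted_mask).
    """
    points = np.ascontiguousarray(points, dtype=np.float64)
    normals = np.ascontiguousarray(normals, dtype=np.float64)
    n = len(points)
    tree = cKDTree(points)
    k = min(max_neighbors, n)
    nb_idx = np.zeros((n, k), dtype=np.int64)
    nb_count = np.zeros(n, dtype=np.int64)
    for start in range(0, n, 100_000):
        stop = min(start + 100_000, n)
        dist, idx = tree.query(points[start:stop], k=k, distance_upper_bound=radius)
        dist = dist.reshape(stop - start, -1)
        idx = idx.reshape(stop - start, -1)
        valid = np.isfinite(dist)
        nb_count[start:stop] = valid.sum(axis=1)
        idx[~valid] = 0
        nb_idx[start:stop] = idx
    return _mls_kernel(points, normals, nb_idx, nb_count, min_fit)


def reorient_normals(points: np.ndarray, normals: np.ndarray, k: int = 8):
    """Flip 'rogue' normals by consistency propagation over a spanning tree.

    Builds a k-NN graph weighted by normal disagreement, extracts a minimum
    spanning tree and propagates orientation from the root breadth-first,
    flipping any normal that disagrees with its tree parent.  The root keeps
    its input orientation, so a cloud that is already consistently oriented
    is returned unchanged.
    """
    n = len(points)
    if n < 2:
        return normals.copy()
    tree = cKDTree(points)
    k = min(k + 1, n)
    _, idx = tree.query(points, k=k)
    src = np.repeat(np.arange(n), k - 1)
    dst = idx[:, 1:].ravel()
    w = 1.0 + 1e-6 - np.abs(np.einsum("ij,ij->i", normals[src], normals[dst]))
    graph = sparse.csr_matrix((w, (src, dst)), shape=(n, n))
    mst = minimum_spanning_tree(graph)
    order, preds = breadth_first_order(mst, 0, directed=False)
    out = normals.copy()
    for node in order[1:]:
        p = preds[node]
        if np.dot(out[node], out[p]) < 0:
            out[node] = -out[node]
    return out


def grid_resample(
    points: np.ndarray,
    cell: float = 0.001,
    normals: np.ndarray | None = None,
    colors: np.ndarray | None = None,
):
    """Reduce redundancy to one point (cell centroid) per occupied cell."""
    return voxel_downsample(points, cell, normals=normals, colors=colors)


def implicit_surface(
    points: np.ndarray,
    normals: np.ndarray,
    depth: int = 9,
    min_samples: int = 10,
    grid_cap: int = 256,
    pad: float = 0.02,
) -> trimesh.Trimesh:
    """Watertight implicit reconstruction of an oriented point set.

    A signed moving-least-squares distance field — the Gaussian-weighted mean
    of point-to-tangent-plane distances over the ``min_samples`` nearest
    oriented points — is sampled on a uniform grid with 2^depth cells along
    the longest bounding-box axis (capped at ``grid_cap``) and polygonised at
    the zero level with marching cubes.  A coarse pass localises the zero
    crossing so the exact field is only evaluated in a narrow band.  The
    largest connected component of the result is returned.
    """
    points = np.asarray(points, dtype=float)
    normals = np.asarray(normals, dtype=float)
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    extent = float(np.max(hi - lo))
    cell = extent / min(2**depth, grid_cap)
    dims = np.maximum(np.ceil((hi - lo) / cell).astype(int) + 1, 2)
    axes = [lo[k] + np.arange(dims[k]) * cell for k in range(3)]

    tree = cKDTree(points)
    k = min(min_samples, len(points))

    def _field(q, kk):
        dist, idx = tree.query(q, k=kk)
        dist = dist.reshape(len(q), -1)
        idx = idx.reshape(len(q), -1)
        diff = q[:, None, :] - points[idx]
        plane = np.einsum("nkj,nkj->nk", diff, normals[idx])
        h = np.maximum(dist[:, :1], 1e-9)
        w = np.exp(-((dist / h) ** 2))
        signed = np.einsum("nk,nk->n", w, plane) / w.sum(axis=1)
        return signed

    # coarse pass every s-th grid node
    s = 4
    coarse_axes = [ax[::s] if len(ax[::s]) > 1 else ax for ax in axes]
    cg = np.meshgrid(*coarse_axes, indexing="ij")
    cq = np.column_stack([g.ravel() for g in cg])
    coarse = _field(cq, 1).reshape([len(a) for a in coarse_axes])

    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        coarse_axes, coarse, bounds_error=False, fill_value=None
    )
    fg = np.meshgrid(*axes, indexing="ij")
    fq = np.column_stack([g.ravel() for g in fg])
    field = interp(fq)
    band = np.abs(field) < 2.0 * s * cell
    if np.any(band):
        field[band] = _field(fq[band], k)
    field = field.reshape(dims)

    verts, faces, _, _ = measure.marching_cubes(field, level=0.0, spacing=(cell,) * 3)
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda m: len(m.vertices))
    return mesh


def clip_excess(
    mesh: trimesh.Trimesh, points: np.ndarray, max_dist: float = 0.005
) -> trimesh.Trimesh:
    """Remove triangles whose centroid is farther than ``max_dist`` from the
    input points (the implicit surface's closure of unobserved regions)."""
    tree = cKDTree(points)
    d, _ = tree.query(mesh.triangles_center)
    keep = d <= max_dist
    out = mesh.copy()
    out.update_faces(keep)
    out.remove_unreferenced_vertices()
    return out


def poisson_mesh(
    points: np.ndarray,
    normals: np.ndarray,
    depth: int = 9,
    min_samples: int = 10,
    clip_dist: float = 0.005,
    grid_cap: int = 256,
):
    """Implicit meshing plus excess-surface clipping.

    Returns ``(clipped_mesh, watertight_mesh)``; the watertight mesh is the
    raw implicit reconstruction before clipping.
    """
    watertight = implicit_surface(
        points, normals, depth=depth, min_samples=min_samples, grid_cap=grid_cap
    )
    clipped = clip_excess(watertight, points, max_dist=clip_dist)
    return clipped, watertight


# ---------------------------------------------------------------------------
# colour reintegration


@njit(cache=True)
def _hue_seq_kernel(h, valid):  # pragma: no cover
    """Sequential shortest-arc averaging of hue rows in [0,1)."""
    n = h.shape[0]
    out = np.zeros(n)
    for i in range(n):
        count = 0
        m = 0.0
        for j in range(h.shape[1]):
            if not valid[i, j]:
                continue
            if count == 0:
                m = h[i, j]
            else:
                d = h[i, j] - m
                if d > 0.5:
                    d -= 1.0
                elif d < -0.5:
                    d += 1.0
                m = m + d / (count + 1)
                m = m % 1.0
            count += 1
        out[i] = m % 1.0
    return out


def sequential_hue_mean(hues_deg) -> float:
    """Shortest-arc sequential average of hue values given in degrees."""
    h = np.asarray(hues_deg, dtype=float)[None, :] / 360.0
    valid = np.ones_like(h, dtype=bool)
    return float(_hue_seq_kernel(h % 1.0, valid)[0] * 360.0)


def reintegrate_color(
    mesh: trimesh.Trimesh,
    points: np.ndarray,
    colors: np.ndarray,
    radius: float = 0.003,
    max_neighbors: int = 32,
) -> trimesh.Trimesh:
    """Assign vertex colours from nearby points in HSV space.

    Saturation and value are averaged arithmetically; hue, being circular, is
    averaged sequentially along the shortest arc between the running mean and
    each neighbour, neighbours taken in ascending point-index order.  A
    vertex with no neighbour inside ``radius`` falls back to its single
    nearest point's colour.
    """
    verts = mesh.vertices
    tree = cKDTree(points)
    k = min(max_neighbors, len(points))
    dist, idx = tree.query(verts, k=k, distance_upper_bound=radius)
    dist = dist.reshape(len(verts), -1)
    idx = idx.reshape(len(verts), -1)
    valid = np.isfinite(dist)
    # fallback: nearest point regardless of radius
    empty = ~valid.any(axis=1)
    if np.any(empty):
        _, nn = tree.query(verts[empty], k=1)
        idx[empty, 0] = nn
        valid[empty, 0] = True
    idx_sorted = np.where(valid, idx, np.iinfo(np.int64).max)
    order = np.argsort(idx_sorted, axis=1)
    idx = np.take_along_axis(idx_sorted, order, axis=1)
    valid = np.take_along_axis(valid, order, axis=1)
    idx[~valid] = 0

    hsv = rgb2hsv(np.clip(colors, 0, 1)[None])[0]
    h = hsv[:, 0][idx]
    s = hsv[:, 1][idx]
    v = hsv[:, 2][idx]
    counts = valid.sum(axis=1)
    s_mean = np.where(valid, s, 0).sum(axis=1) / counts
    v_mean = np.where(valid, v, 0).sum(axis=1) / counts
    h_mean = _hue_seq_kernel(np.ascontiguousarray(h), np.ascontiguousarray(valid))
    rgb = hsv2rgb(np.stack([h_mean, s_mean, v_mean], axis=1)[None])[0]
    out = mesh.copy()
    out.visual = trimesh.visual.ColorVisuals(
        out, vertex_colors=(np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    )
    return out
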