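"""Coarse embedded deformation graphs from full-resolution clouds.

A deformation graph is a voxel-downsampled, triangulated version of one
frame's point cloud.  Each node carries a 4x3 affine transform (3x3 linear
block stacked over a 1x3 translation row, acting on row vectors) that the
nonrigid optimiser estimates; the graph's edges define the stiffness
regulariser's neighbourhoods and its single-face ("border") edges mark the
open boundary used for correspondence rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay

from .camera import CameraIntrinsics
from .preprocess import ColoredPointCloud, RGBDFrame

__all__ = [
    "DeformationGraph",
    "estimate_normals",
    "voxel_downsample",
    "triangulate",
    "prune_components",
    "build_graph",
    "identity_transforms",
    "apply_transforms",
    "transform_normals",
    "faces_to_edges",
    "border_edges",
]


def identity_transforms(n: int) -> np.ndarray:
    """(n,4,3) stack of identity affine transforms (A=I, t=0)."""
    X = np.zeros((n, 4, 3))
    X[:, :3, :] = np.eye(3)
    return X


def apply_transforms(points: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Map each point by its own 4x3 transform: p' = p·A + t."""
    return np.einsum("ij,ijk->ik", points, X[:, :3, :]) + X[:, 3, :]


def transform_normals(normals: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Map normals by the per-node linear block, renormalised."""
    n = np.einsum("ij,ijk->ik", normals, X[:, :3, :])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return n / norms


def faces_to_edges(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges (E,2), each row sorted ascending, rows sorted."""
    faces = np.asarray(faces, dtype=np.int64)
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def border_edges(faces: np.ndarray) -> np.ndarray:
    """Edges belonging to exactly one face (the open boundary Ψ)."""
    faces = np.asarray(faces, dtype=np.int64)
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]])
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq[counts == 1]


@dataclass
class DeformationGraph:
    """Downsampled triangulated node set with per-node affine transforms."""

    nodes: np.ndarray  # (J,3) world coordinates
    node_normals: np.ndarray  # (J,3) unit
    faces: np.ndarray  # (F,3) node indices
    X: np.ndarray = None  # (J,4,3) per-node affine transform
    edges: np.ndarray = field(init=False)
    psi: np.ndarray = field(init=False)  # border edges, subset of `edges`

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.nodes):
            raise ValueError("face index out of range")
        if self.X is None:
            self.X = identity_transforms(len(self.nodes))
        self.edges = faces_to_edges(self.faces) if self.faces.size else np.zeros((0, 2), np.int64)
        self.psi = border_edges(self.faces) if self.faces.size else np.zeros((0, 2), np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def warped_nodes(self) -> np.ndarray:
        return apply_transforms(self.nodes, self.X)

    def warped_normals(self) -> np.ndarray:
        return transform_normals(self.node_normals, self.X)

    def border_vertex_set(self) -> np.ndarray:
        """Boolean mask of nodes incident to a border edge."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        if self.psi.size:
            mask[self.psi.ravel()] = True
        return mask


# ---------------------------------------------------------------------------
# normals from the projective pixel grid


def estimate_normals(
    frame: RGBDFrame, intr: CameraIntrinsics, cloud: ColoredPointCloud
) -> ColoredPointCloud:
    """Per-point normals by PCA over the 3x3 projective depth window.

    The normal of a point is the smallest-eigenvalue eigenvector of the
    covariance of the valid backprojected points in its 3x3 pixel
    neighbourhood, flipped so it faces the camera origin (dot(point, normal)
    < 0).  Points with fewer than 3 valid window neighbours are dropped.
    """
    if cloud.pixels is None:
        raise ValueError("cloud lacks pixel provenance")
    H, W = frame.depth.shape
    # dense grid of backprojected positions for all valid pixels
    grid = np.full((H, W, 3), np.nan)
    sel = frame.depth > 0
    vv, uu = np.nonzero(sel)
    d = frame.depth[vv, uu]
    pts_all = intr.backproject(np.column_stack([uu, vv]).astype(float), d)
    grid[vv, uu] = pts_all

    u, v = cloud.pixels[:, 0], cloud.pixels[:, 1]
    n_pts = len(u)
    acc = np.zeros((n_pts, 3))
    acc2 = np.zeros((n_pts, 3, 3))
    count = np.zeros(n_pts)
    padded = np.full((H + 2, W + 2, 3), np.nan)
    padded[1:-1, 1:-1] = grid
    for dv in (-1, 0, 1):
        for du in (-1, 0, 1):
            nb = padded[v + 1 + dv, u + 1 + du]
            ok = np.isfinite(nb[:, 0])
            nb0 = np.where(ok[:, None], nb, 0.0)
            acc += nb0
            acc2 += np.einsum("ni,nj->nij", nb0, nb0)
            count += ok
    keep = count >= 3
    if not np.any(keep):
        raise ValueError("no point has enough window neighbours for a normal")
    c = count[keep]
    mean = acc[keep] / c[:, None]
    cov = acc2[keep] / c[:, None, None] - np.einsum("ni,nj->nij", mean, mean)
    # smallest-eigenvalue eigenvector of each symmetric 3x3 covariance
    w, vec = np.linalg.eigh(cov)
    normals = vec[:, :, 0]
    pts = cloud.points[keep]
    flip = np.einsum("ni,ni->n", pts, normals) > 0
    normals[flip] *= -1.0
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / norms
    return ColoredPointCloud(
        pts,
        colors=None if cloud.colors is None else cloud.colors[keep],
        normals=normals,
        frame_index=cloud.frame_index,
        pixels=cloud.pixels[keep],
    )


# ---------------------------------------------------------------------------
# downsampling and triangulation


def voxel_downsample(
    points: np.ndarray,
    cell: float = 0.006,
    normals: np.ndarray | None = None,
    colors: np.ndarray | None = None,
):
    """Voxel-grid averaging: one output per occupied cell, at the centroid.

    Normals are averaged then renormalised.  Returns (points[, normals]
    [, colors]) with outputs ordered by lexicographically sorted cell key, so
    the result is deterministic for a given input.
    """
    if cell <= 0:
        raise ValueError("cell size must be positive")
    points = np.asarray(points, dtype=float)
    keys = np.floor(points / cell).astype(np.int64)
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    n_cells = len(uniq)
    counts = np.bincount(inv, minlength=n_cells).astype(float)

    def _avg(arr):
        out = np.zeros((n_cells, arr.shape[1]))
        for k in range(arr.shape[1]):
            out[:, k] = np.bincount(inv, weights=arr[:, k], minlength=n_cells)
        return out / counts[:, None]

    out_pts = _avg(points)
    results = [out_pts]
    if normals is not None:
        nrm = _avg(np.asarray(normals, dtype=float))
        norms = np.linalg.norm(nrm, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        results.append(nrm / norms)
    if colors is not None:
        results.append(_avg(np.asarray(colors, dtype=float)))
    return tuple(results) if len(results) > 1 else out_pts


def _parameterize(nodes: np.ndarray, mode: str, radius: float):
    """2D parameterisation of a near-planar or near-cylindrical node set."""
    c = nodes.mean(axis=0)
    q = nodes - c
    _, s, Vt = np.linalg.svd(q, full_matrices=False)
    if mode == "auto":
        # near-planar if the extent along the smallest principal axis is
        # below the triangulation radius
        thickness = np.abs(q @ Vt[2])
        mode = "plane" if thickness.max() < radius else "cylinder"
    if mode == "plane":
        return np.column_stack([q @ Vt[0], q @ Vt[1]])
    # cylindrical unwrap about the dominant (vertical) axis; the angular
    # centre is a Kasa circle fit in the cross-sectional plane (the patch
    # centroid sits near the surface for wide views and would fold theta)
    axis, e2, e3 = Vt[0], Vt[1], Vt[2]
    h = q @ axis
    x, y = q @ e2, q @ e3
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (cx, cy, _), *_ = np.linalg.lstsq(A, b, rcond=None)
    x, y = x - cx, y - cy
    theta = np.arctan2(y, x)
    # rotate the seam into the largest angular gap so no edge crosses it
    order = np.argsort(theta)
    gaps = np.diff(theta[order])
    wrap_gap = theta[order[0]] + 2 * np.pi - theta[order[-1]]
    if gaps.size and gaps.max() > wrap_gap:
        seam = theta[order[np.argmax(gaps)]] + gaps.max() / 2
    else:
        seam = np.pi
    theta = np.mod(theta - seam + np.pi, 2 * np.pi) - np.pi
    r_mean = np.hypot(x, y).mean()
    return np.column_stack([theta * max(r_mean, 1e-6), h])


def triangulate(
    nodes: np.ndarray,
    radius: float = 0.025,
    normals: np.ndarray | None = None,
    mode: str = "auto",
) -> np.ndarray:
    """Triangulate a node set; no face edge longer than ``radius``.

    Delaunay triangulation of a 2D projective parameterisation (tangent plane
    for near-planar patches, cylindrical unwrap otherwise), followed by
    pruning of faces with any 3D edge exceeding the search radius.  Faces are
    oriented consistently with the supplied node normals when given.
    """
    nodes = np.asarray(nodes, dtype=float)
    if len(nodes) < 3:
        raise ValueError("need at least 3 nodes to triangulate")
    uv = _parameterize(nodes, mode, radius)
    tri = Delaunay(uv)
    faces = tri.simplices.astype(np.int64)
    a, b, c = nodes[faces[:, 0]], nodes[faces[:, 1]], nodes[faces[:, 2]]
    lens = np.stack(
        [
            np.linalg.norm(a - b, axis=1),
            np.linalg.norm(b - c, axis=1),
            np.linalg.norm(c - a, axis=1),
        ]
    )
    area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
    faces = faces[(lens.max(axis=0) <= radius) & (area2 > 1e-14)]
    if normals is not None and faces.size:
        fn = np.cross(nodes[faces[:, 1]] - nodes[faces[:, 0]],
                      nodes[faces[:, 2]] - nodes[faces[:, 0]])
        ref = normals[faces].mean(axis=1)
        flip = np.einsum("ni,ni->n", fn, ref) < 0
        faces[flip] = faces[flip][:, [0, 2, 1]]
    return faces


def prune_components(nodes: np.ndarray, faces: np.ndarray, *extras):
    """Keep only the largest connected component of the triangulated set.

    Ties in component size are broken by the component containing the lowest
    original node index.  Isolated nodes (in no face) form their own
    single-node components and are pruned with the rest.  Extra per-node
    arrays are filtered consistently.
    """
    J = len(nodes)
    edges = faces_to_edges(faces)
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(J, J)
    )
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = np.max(sizes)
    # tie-break: among components of maximal size, lowest minimum node index;
    # scanning node indices ascending finds it first
    winner = labels[np.argmax(sizes[labels] == best)]
    keep = labels == winner
    new_index = -np.ones(J, dtype=np.int64)
    new_index[keep] = np.arange(keep.sum())
    kept_faces = faces[np.all(keep[faces], axis=1)]
    out = [nodes[keep], new_index[kept_faces]]
    out.extend(e[keep] for e in extras)
    return tuple(out)


def build_graph(
    points_world: np.ndarray,
    normals_world: np.ndarray,
    cell: float = 0.006,
    radius: float = 0.025,
    mode: str = "auto",
) -> DeformationGraph:
    """Voxel downsample -> triangulate -> prune, yielding a deformation graph."""
    nodes, nrm = voxel_downsample(points_world, cell, normals=normals_world)
    faces = triangulate(nodes, radius=radius, normals=nrm, mode=mode)
    nodes, faces, nrm = prune_components(nodes, faces, nrm)
    return DeformationGraph(nodes=nodes, node_normals=nrm, faces=faces)
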