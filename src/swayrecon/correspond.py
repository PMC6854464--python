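"""Data association between deformation graphs.

Two variants are provided: classic closest-vertex correspondences, and
shortest-distance correspondences where each source node is matched to the
exact nearest point on the target's triangulated surface — a vertex, a point
on an edge, or a point inside a face.  On coarse graphs the surface hit is a
strictly better match than the nearest vertex and yields visibly better
alignment.

Rejection clips a correspondence when it is too far (d >= d_max), when it
lands on the target's open boundary (a sign of non-overlap between the two
partial scans), or when the normals disagree by more than a threshold angle
(a sign of matching the wrong geometric layer, e.g. armpit against arm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .graphs import DeformationGraph

__all__ = [
    "CorrespondenceSet",
    "point_triangle_closest",
    "closest_point_on_triangles",
    "MeshDistanceQuery",
    "shortest_distance_correspondences",
    "closest_point_correspondences",
    "reject",
]

REGION_FACE = 0
REGION_EDGE = 1
REGION_VERTEX = 2


def closest_point_on_triangles(p: np.ndarray, tri: np.ndarray):
    """Exact closest point on each triangle, vectorised over pairs.

    Parameters
    ----------
    p : (N,3) query points
    tri : (N,3,3) triangle vertices (a, b, c) per query

    Returns
    -------
    closest : (N,3) closest point on the triangle
    bary : (N,3) barycentric coordinates of the closest point
    region : (N,) REGION_FACE / REGION_EDGE / REGION_VERTEX
    sub : (N,) vertex index (0..2) or edge index (0=ab, 1=bc, 2=ca); -1 for face

    The classification of the closest point into vertex/edge/face regions of
    the triangle's Voronoi diagram gives the same point as projecting onto the
    supporting plane and then, when outside, onto the nearest clamped edge.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    tri = np.asarray(tri, dtype=float).reshape(-1, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    n = len(p)
    bary = np.zeros((n, 3))
    region = np.full(n, REGION_FACE, dtype=np.int8)
    sub = np.full(n, -1, dtype=np.int8)
    done = np.zeros(n, dtype=bool)

    def _set(mask, bar, reg, s):
        m = mask & ~done
        if np.any(m):
            bary[m] = bar if np.ndim(bar) == 1 else bar[m]
            region[m] = reg
            sub[m] = s if np.isscalar(s) else s[m]
            done[m] = True

    _set((d1 <= 0) & (d2 <= 0), np.array([1.0, 0.0, 0.0]), REGION_VERTEX, 0)
    _set((d3 >= 0) & (d4 <= d3), np.array([0.0, 1.0, 0.0]), REGION_VERTEX, 1)
    _set((d6 >= 0) & (d5 <= d6), np.array([0.0, 0.0, 1.0]), REGION_VERTEX, 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = d1 / (d1 - d3)
        t_ac = d2 / (d2 - d6)
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    bar_ab = np.column_stack([1 - t_ab, t_ab, np.zeros(n)])
    bar_ac = np.column_stack([1 - t_ac, np.zeros(n), t_ac])
    bar_bc = np.column_stack([np.zeros(n), 1 - t_bc, t_bc])
    _set((vc <= 0) & (d1 >= 0) & (d3 <= 0), bar_ab, REGION_EDGE, 0)
    _set((vb <= 0) & (d2 >= 0) & (d6 <= 0), bar_ac, REGION_EDGE, 2)
    _set((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), bar_bc, REGION_EDGE, 1)

    inside = ~done
    if np.any(inside):
        denom = va + vb + vc
        v = vb[inside] / denom[inside]
        w = vc[inside] / denom[inside]
        bary[inside] = np.column_stack([1 - v - w, v, w])
    closest = np.einsum("nk,nkj->nj", bary, tri)
    return closest, bary, region, sub


def point_triangle_closest(p, f1, f2, f3):
    """Closest point on a single triangle and its region classification.

    Returns ``(closest_point, region_string)`` where region is ``"face"``,
    ``"edge_k"`` or ``"vertex_k"`` with k the local index.  Raises for a
    degenerate (near-zero-area) triangle.
    """
    f1, f2, f3 = (np.asarray(f, dtype=float) for f in (f1, f2, f3))
    area = 0.5 * np.linalg.norm(np.cross(f2 - f1, f3 - f1))
    if area <= 1e-12:
        raise ValueError("degenerate triangle (area <= 1e-12)")
    closest, _, region, sub = closest_point_on_triangles(
        np.asarray(p, dtype=float)[None], np.stack([f1, f2, f3])[None]
    )
    name = {REGION_FACE: "face", REGION_EDGE: f"edge_{sub[0]}",
            REGION_VERTEX: f"vertex_{sub[0]}"}[int(region[0])]
    return closest[0], name


@njit(cache=True)
def _closest_scalar(px, py, pz, tri):  # pragma: no cover
    """Scalar Ericson closest-point; returns (x,y,z, b0,b1,b2, region, sub)."""
    ax, ay, az = tri[0, 0], tri[0, 1], tri[0, 2]
    bx, by, bz = tri[1, 0], tri[1, 1], tri[1, 2]
    cx, cy, cz = tri[2, 0], tri[2, 1], tri[2, 2]
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return ax, ay, az, 1.0, 0.0, 0.0, REGION_VERTEX, 0
    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bx, by, bz, 0.0, 1.0, 0.0, REGION_VERTEX, 1
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cx, cy, cz, 0.0, 0.0, 1.0, REGION_VERTEX, 2
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        t = d1 / (d1 - d3)
        return (ax + t * abx, ay + t * aby, az + t * abz,
                1.0 - t, t, 0.0, REGION_EDGE, 0)
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        t = d2 / (d2 - d6)
        return (ax + t * acx, ay + t * acy, az + t * acz,
                1.0 - t, 0.0, t, REGION_EDGE, 2)
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return (bx + t * (cx - bx), by + t * (cy - by), bz + t * (cz - bz),
                0.0, 1.0 - t, t, REGION_EDGE, 1)
    denom = va + vb + vc
    v = vb / denom
    w = vc / denom
    qx = ax + abx * v + acx * w
    qy = ay + aby * v + acy * w
    qz = az + abz * v + acz * w
    return qx, qy, qz, 1.0 - v - w, v, w, REGION_FACE, -1


@njit(cache=True)
def _best_triangle_kernel(pts, tri, centroids, radii, bounds,
                          cand_indptr, cand_indices):  # pragma: no cover
    """Exact per-query minimum over candidate triangles.

    A candidate f is evaluated only if it can beat the current best:
    dist(p, centroid_f) - r_f < best.  Candidate lists are sorted ascending
    so equal distances break to the lowest face index.
    """
    n = pts.shape[0]
    out_pt = np.empty((n, 3))
    out_bary = np.empty((n, 3))
    out_dist = np.empty(n)
    out_face = np.empty(n, dtype=np.int64)
    out_region = np.empty(n, dtype=np.int8)
    out_sub = np.empty(n, dtype=np.int8)
    for i in range(n):
        px, py, pz = pts[i, 0], pts[i, 1], pts[i, 2]
        best = bounds[i] + 1e-12
        bf = -1
        bx = by = bz = 0.0
        b0 = b1 = b2 = 0.0
        breg = np.int8(0)
        bsub = np.int8(-1)
        for jj in range(cand_indptr[i], cand_indptr[i + 1]):
            f = cand_indices[jj]
            dcx = px - centroids[f, 0]
            dcy = py - centroids[f, 1]
            dcz = pz - centroids[f, 2]
            lower = np.sqrt(dcx * dcx + dcy * dcy + dcz * dcz) - radii[f]
            if lower >= best:
                continue
            qx, qy, qz, w0, w1, w2, reg, sub = _closest_scalar(px, py, pz, tri[f])
            dx, dy, dz = px - qx, py - qy, pz - qz
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < best:
                best = d
                bf = f
                bx, by, bz = qx, qy, qz
                b0, b1, b2 = w0, w1, w2
                breg = np.int8(reg)
                bsub = np.int8(sub)
        out_pt[i, 0], out_pt[i, 1], out_pt[i, 2] = bx, by, bz
        out_bary[i, 0], out_bary[i, 1], out_bary[i, 2] = b0, b1, b2
        out_dist[i] = best
        out_face[i] = bf
        out_region[i] = breg
        out_sub[i] = bsub
    return out_pt, out_bary, out_dist, out_face, out_region, out_sub


class MeshDistanceQuery:
    """Exact closest-point-on-surface queries against a triangle mesh.

    A KD-tree over triangle centroids provides candidates: an upper bound on
    the surface distance comes from the nearest few centroids' triangles, and
    every triangle whose centroid lies within ``bound + R_max`` (R_max = the
    largest centroid-to-vertex radius in the mesh) is then tested exactly, so
    the globally closest triangle can never be missed.  Ties between
    equidistant faces break to the lowest face index.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        if len(faces) == 0:
            raise ValueError("target mesh has no faces")
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tri = np.ascontiguousarray(self.vertices[self.faces])
        self.centroids = np.ascontiguousarray(self.tri.mean(axis=1))
        self.radii = np.ascontiguousarray(
            np.linalg.norm(self.tri - self.centroids[:, None, :], axis=2).max(axis=1)
        )
        # a handful of oversized faces (e.g. cap fans) would blow up the ball
        # radius for every query; they are instead appended to every
        # candidate list and culled by the kernel's lower-bound check
        r_med = np.median(self.radii)
        self.big = np.flatnonzero(self.radii > max(4.0 * r_med, 1e-12))
        small_radii = np.delete(self.radii, self.big)
        self.r_max = float(small_radii.max()) if small_radii.size else 0.0
        self.tree = cKDTree(self.centroids)

    def query(self, pts: np.ndarray, batch: int = 65536):
        """Return (closest (N,3), dist (N,), face (N,), bary (N,3), region, sub)."""
        pts = np.ascontiguousarray(np.atleast_2d(np.asarray(pts, dtype=float)))
        outs = [self._query_batch(pts[s:s + batch])
                for s in range(0, len(pts), batch)]
        return tuple(np.concatenate(parts) for parts in zip(*outs))

    def _query_batch(self, pts: np.ndarray):
        n = len(pts)
        k0 = min(4, len(self.faces))
        _, idx0 = self.tree.query(pts, k=k0)
        idx0 = np.atleast_2d(idx0.reshape(n, -1))
        q0 = np.repeat(np.arange(n), idx0.shape[1])
        f0 = idx0.ravel()
        c0, _, _, _ = closest_point_on_triangles(pts[q0], self.tri[f0])
        d0 = np.linalg.norm(c0 - pts[q0], axis=1).reshape(n, -1)
        bound = d0.min(axis=1)

        balls = self.tree.query_ball_point(pts, bound + self.r_max + 1e-12)
        nbig = len(self.big)
        counts = np.fromiter((len(b) for b in balls), dtype=np.int64, count=n) + nbig
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        if nbig:
            fidx = np.concatenate(
                [np.concatenate([np.sort(b), self.big]) for b in balls]
            ).astype(np.int64)
        else:
            fidx = (np.concatenate([np.sort(b) for b in balls]).astype(np.int64)
                    if counts.sum() else np.zeros(0, np.int64))
        closest, bary, dist, face, region, sub = _best_triangle_kernel(
            pts, self.tri, self.centroids, self.radii, bound, indptr, fidx
        )
        return closest, dist, face, bary, region, sub


@dataclass
class CorrespondenceSet:
    """Per-source-node match against the target surface."""

    target_points: np.ndarray  # (J,3) on-surface hit g''
    target_normals: np.ndarray  # (J,3) interpolated unit normal n''
    weights: np.ndarray  # (J,) in {0,1}
    distances: np.ndarray  # (J,)
    faces: np.ndarray  # (J,) target face index of the hit (-1 for vertex variant)
    bary: np.ndarray  # (J,3) barycentric coords of the hit
    region: np.ndarray  # (J,) REGION_* codes
    sub: np.ndarray  # (J,) local vertex/edge index of the hit

    @property
    def n_accepted(self) -> int:
        return int(np.sum(self.weights > 0))


def _interp_normals(target: DeformationGraph, faces, bary, warped=True):
    node_normals = target.warped_normals() if warped else target.node_normals
    n = np.einsum("nk,nkj->nj", bary, node_normals[target.faces[faces]])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return n / norms


def shortest_distance_correspondences(
    source: DeformationGraph, target: DeformationGraph,
    query: MeshDistanceQuery | None = None,
) -> CorrespondenceSet:
    """Match each transformed source node to the closest target surface point.

    The target normal at the hit is the barycentric interpolation of the
    target's vertex normals.  A prebuilt ``MeshDistanceQuery`` over the
    target may be passed to amortise the spatial index across iterations.
    """
    if len(target.faces) == 0:
        raise ValueError("target graph has no faces")
    if query is None:
        query = MeshDistanceQuery(target.warped_nodes(), target.faces)
    src = source.warped_nodes()
    closest, dist, fidx, bary, region, sub = query.query(src)
    normals = _interp_normals(target, fidx, bary)
    return CorrespondenceSet(
        target_points=closest,
        target_normals=normals,
        weights=np.ones(len(src)),
        distances=dist,
        faces=fidx,
        bary=bary,
        region=region,
        sub=sub,
    )


def closest_point_correspondences(
    source: DeformationGraph, target: DeformationGraph,
    tree: cKDTree | None = None,
) -> CorrespondenceSet:
    """Baseline variant: match each source node to the nearest target vertex."""
    tgt = target.warped_nodes()
    if tree is None:
        tree = cKDTree(tgt)
    src = source.warped_nodes()
    dist, vidx = tree.query(src)
    J = len(src)
    bary = np.zeros((J, 3))
    bary[:, 0] = 1.0
    return CorrespondenceSet(
        target_points=tgt[vidx],
        target_normals=target.warped_normals()[vidx],
        weights=np.ones(J),
        distances=dist,
        faces=np.full(J, -1, dtype=np.int64),
        bary=bary,
        region=np.full(J, REGION_VERTEX, dtype=np.int8),
        sub=vidx.astype(np.int64),  # global vertex index in the vertex variant
    )


def _edge_key(edges: np.ndarray, J: int) -> np.ndarray:
    e = np.sort(edges, axis=1)
    return e[:, 0].astype(np.int64) * J + e[:, 1]


def reject(
    corrs: CorrespondenceSet,
    target: DeformationGraph,
    source_normals: np.ndarray,
    d_max: float = 0.02,
    angle_max_deg: float = 45.0,
) -> CorrespondenceSet:
    """Zero the weight of unreliable correspondences.

    A match is kept only if (i) its distance is below ``d_max``, (ii) the hit
    does not lie on the target's open boundary (a border edge, or a vertex
    incident to one), and (iii) the source and interpolated target normals
    agree to within ``angle_max_deg``.  Idempotent; weights only ever drop.
    """
    w = corrs.weights.copy()
    w[corrs.distances >= d_max] = 0.0

    border_vertex = target.border_vertex_set()
    J = target.n_nodes
    psi_keys = _edge_key(target.psi, J) if target.psi.size else np.zeros(0, np.int64)

    on_face = corrs.faces >= 0
    # vertex hits: border if the vertex touches a border edge
    vmask = corrs.region == REGION_VERTEX
    vm_f = vmask & on_face
    if np.any(vm_f):
        vids = target.faces[corrs.faces[vm_f], corrs.sub[vm_f]]
        w[np.nonzero(vm_f)[0][border_vertex[vids]]] = 0.0
    vm_g = vmask & ~on_face  # closest-vertex variant stores global index in sub
    if np.any(vm_g):
        w[np.nonzero(vm_g)[0][border_vertex[corrs.sub[vm_g]]]] = 0.0
    # edge hits: border if the edge belongs to exactly one face
    emask = (corrs.region == REGION_EDGE) & on_face
    if np.any(emask) and psi_keys.size:
        f = target.faces[corrs.faces[emask]]
        s = corrs.sub[emask]
        e = np.column_stack([f[np.arange(len(f)), s], f[np.arange(len(f)), (s + 1) % 3]])
        hit_border = np.isin(_edge_key(e, J), psi_keys)
        w[np.nonzero(emask)[0][hit_border]] = 0.0

    sn = np.asarray(source_normals, dtype=float)
    cosang = np.clip(np.einsum("ij,ij->i", sn, corrs.target_normals), -1.0, 1.0)
    w[np.degrees(np.arccos(cosang)) >= angle_max_deg] = 0.0

    return CorrespondenceSet(
        target_points=corrs.target_points,
        target_normals=corrs.target_normals,
        weights=w,
        distances=corrs.distances,
        faces=corrs.faces,
        bary=corrs.bary,
        region=corrs.region,
        sub=corrs.sub,
    )
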