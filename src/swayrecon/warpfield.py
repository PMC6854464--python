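"""Interpolate per-node affine transforms to arbitrary 3D points.

The embedded-deformation warp averages, over the M nearest graph nodes, the
node-relative affine maps

    v' = sum_j  w_j(v) [ Rbar_j (v - g_j) + g_j + tbar_j ]

with radially decaying weights w_j ∝ (1 - ||v - g_j|| / d_max)^2, d_max being
the distance to the farthest of the M nearest nodes (whose weight is thereby
exactly zero), normalised to sum to one.  Normals are mapped by the linear
blocks only and renormalised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .graphs import DeformationGraph

__all__ = ["WarpField", "node_relative_transforms"]


def node_relative_transforms(nodes: np.ndarray, X: np.ndarray):
    """Convert optimiser transforms to node-relative (Rbar, tbar) form.

    The optimiser's X_j acts on absolute homogeneous row vectors:
    mapped(v) = v·A_j + t_j with A_j = X_j[:3], t_j = X_j[3].  In column
    vector form the linear map is Rbar_j = A_j^T and the node-relative
    translation is tbar_j = mapped(g_j) - g_j, so that
    Rbar_j (v - g_j) + g_j + tbar_j == mapped(v) for every v.
    """
    A = np.asarray(X)[:, :3, :]
    t = np.asarray(X)[:, 3, :]
    Rbar = np.transpose(A, (0, 2, 1))
    mapped_nodes = np.einsum("ij,ijk->ik", nodes, A) + t
    tbar = mapped_nodes - nodes
    return Rbar, tbar


@dataclass
class WarpField:
    """Smooth warp of 3D space induced by a deformation graph's transforms."""

    nodes: np.ndarray  # (J,3)
    Rbar: np.ndarray  # (J,3,3) linear block, column-vector convention
    tbar: np.ndarray  # (J,3) node-relative translation
    m_nearest: int = 4

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self._tree = cKDTree(self.nodes)

    @classmethod
    def from_graph(cls, graph: DeformationGraph, m_nearest: int = 4) -> "WarpField":
        Rbar, tbar = node_relative_transforms(graph.nodes, graph.X)
        return cls(graph.nodes, Rbar, tbar, m_nearest=m_nearest)

    def _weights(self, pts: np.ndarray):
        """M-nearest node indices and normalised interpolation weights."""
        m = min(self.m_nearest, len(self.nodes))
        dist, idx = self._tree.query(pts, k=m)
        dist = dist.reshape(len(pts), m)
        idx = idx.reshape(len(pts), m)
        d_max = dist[:, -1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(d_max > 0, (1.0 - dist / d_max) ** 2, 1.0)
        total = raw.sum(axis=1, keepdims=True)
        # all M nodes equidistant (or a single node): fall back to uniform
        degenerate = total[:, 0] <= 0
        raw[degenerate] = 1.0
        total = raw.sum(axis=1, keepdims=True)
        return idx, raw / total

    def node_weights(self, v: np.ndarray):
        """Weights of the M nearest nodes for a single query point."""
        idx, w = self._weights(np.atleast_2d(np.asarray(v, dtype=float)))
        return idx[0], w[0]

    def warp(self, pts: np.ndarray) -> np.ndarray:
        """Apply the interpolated deformation to points (N,3).

        Evaluated as v + sum_j w_j [(Rbar_j - I)(v - g_j) + tbar_j], which is
        algebraically identical to the blended node-relative form (the
        weights sum to one) but returns v bit-exactly under an identity
        field.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        idx, w = self._weights(pts)
        g = self.nodes[idx]  # (N,m,3)
        local = pts[:, None, :] - g
        delta = (
            np.einsum("nmij,nmj->nmi", self.Rbar[idx] - np.eye(3), local)
            + self.tbar[idx]
        )
        return pts + np.einsum("nm,nmi->ni", w, delta)

    def warp_normals(self, pts: np.ndarray, normals: np.ndarray) -> np.ndarray:
        """Rotate normals by the blended linear blocks, renormalised."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        normals = np.atleast_2d(np.asarray(normals, dtype=float))
        idx, w = self._weights(pts)
        rotated = np.einsum("nmij,nj->nmi", self.Rbar[idx] - np.eye(3), normals)
        out = normals + np.einsum("nm,nmi->ni", w, rotated)
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return out / norms

    def compose_warp(self, other: "WarpField", pts: np.ndarray) -> np.ndarray:
        """Two-step propagation: apply self (frame level) then other (bundle)."""
        return other.warp(self.warp(pts))
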