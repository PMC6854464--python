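"""Nonrigid ICP over embedded deformation graphs.

Each pairwise alignment estimates one 4x3 affine transform per source node by
iterating {correspond -> reject -> assemble -> solve}.  The linear system
stacks three blocks:

* data rows — accepted correspondences pull each node's transformed position
  (g_i^T, 1) · X_i towards its on-surface target point;
* stiffness rows — alpha-weighted differences of adjacent nodes' transforms
  (graph incidence matrix Kronecker the 4x4 identity) keep the deformation
  locally smooth / as-rigid-as-possible;
* mobility rows — beta-weighted self-correspondences park the nodes whose
  correspondences were all rejected (non-overlap regions), preventing the
  regulariser from flattening unconstrained geometry.

For fixed correspondences the minimiser of ||AX - B||_F^2 is found in closed
form, so the total cost is non-increasing within each solve.  The multi-view
schedule pools frames into bundles of 10, registers each bundle internally to
its first frame, then circularly aligns every bundle graph against the
resampled union of all others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg, lsqr, splu

from .correspond import (
    CorrespondenceSet,
    MeshDistanceQuery,
    closest_point_correspondences,
    reject,
    shortest_distance_correspondences,
)
from .graphs import DeformationGraph, build_graph, identity_transforms

__all__ = [
    "StackedSystem",
    "Bundle",
    "BundleSet",
    "incidence_matrix",
    "assemble",
    "solve",
    "system_cost",
    "pairwise_nricp",
    "bundle_fit",
    "global_fit",
]


def incidence_matrix(graph: DeformationGraph) -> sparse.csr_matrix:
    """Node-arc incidence matrix M (E x J): -1 at the lower node index of
    each edge, +1 at the higher."""
    E, J = len(graph.edges), graph.n_nodes
    rows = np.repeat(np.arange(E), 2)
    cols = graph.edges.ravel()
    vals = np.tile([-1.0, 1.0], E)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(E, J))


@dataclass
class StackedSystem:
    """Sparse stacked least-squares system A X = B for one pairwise alignment."""

    A: sparse.csr_matrix  # (4E + J + J_parked) x 4J
    B: np.ndarray  # matching right-hand side, 3 columns
    J: int
    alpha: float
    beta: float
    n_data: int  # accepted correspondences
    row_slices: dict = field(default_factory=dict)  # block name -> (start, stop)


def assemble(
    source: DeformationGraph,
    corrs: CorrespondenceSet,
    alpha: float = 20.0,
    beta: float = 1.0,
) -> StackedSystem:
    """Stack stiffness, data and mobility blocks into one sparse system.

    Data rows carry the ORIGINAL homogeneous node rows (g_i^T, 1) so that the
    solved X maps original coordinates directly (absolute, not incremental).
    Nodes whose correspondence was rejected appear only in the mobility block.
    """
    J = source.n_nodes
    g = source.nodes
    w = corrs.weights
    accepted = w > 0
    if not np.any(accepted) and alpha == 0 and beta == 0:
        raise ValueError("singular system: no correspondences and no regulariser")

    rows, cols, vals = [], [], []
    b_blocks = []
    r = 0
    slices = {}

    # stiffness block: alpha * (M kron I4)
    E = len(source.edges)
    if E and alpha != 0:
        e = source.edges
        rr = np.repeat(np.arange(E) * 4, 8) + np.tile(np.repeat(np.arange(4), 2), E)
        cc = np.empty(E * 8, dtype=np.int64)
        cc[0::2] = np.repeat(e[:, 0] * 4, 4) + np.tile(np.arange(4), E)
        cc[1::2] = np.repeat(e[:, 1] * 4, 4) + np.tile(np.arange(4), E)
        vv = np.tile([-alpha, alpha], E * 4)
        rows.append(rr + r)
        cols.append(cc)
        vals.append(vv)
        b_blocks.append(np.zeros((4 * E, 3)))
        slices["stiffness"] = (r, r + 4 * E)
        r += 4 * E

    # data block: W * Ghat (rows with w=0 are zero)
    homog = np.column_stack([g, np.ones(J)])
    rr = np.repeat(np.arange(J), 4)
    cc = (np.arange(J * 4)).astype(np.int64)
    vv = (homog * w[:, None]).ravel()
    rows.append(rr + r)
    cols.append(cc)
    vals.append(vv)
    b_blocks.append(corrs.target_points * w[:, None])
    slices["data"] = (r, r + J)
    r += J

    # mobility block: beta * Phat for parked nodes only
    parked = np.nonzero(~accepted)[0]
    if parked.size and beta != 0:
        rr = np.repeat(np.arange(parked.size), 4)
        cc = (np.repeat(parked * 4, 4) + np.tile(np.arange(4), parked.size)).astype(np.int64)
        vv = (homog[parked] * beta).ravel()
        rows.append(rr + r)
        cols.append(cc)
        vals.append(vv)
        b_blocks.append(beta * g[parked])
        slices["mobility"] = (r, r + parked.size)
        r += parked.size

    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(r, 4 * J),
    )
    B = np.vstack(b_blocks)
    return StackedSystem(
        A=A, B=B, J=J, alpha=alpha, beta=beta,
        n_data=int(accepted.sum()), row_slices=slices,
    )


def system_cost(sys: StackedSystem, X: np.ndarray) -> dict:
    """Total and per-block squared-Frobenius cost of X under the system."""
    Xf = X.reshape(4 * sys.J, 3)
    res = sys.A @ Xf - sys.B
    out = {"total": float(np.sum(res**2))}
    for name, (a, b) in sys.row_slices.items():
        out[name] = float(np.sum(res[a:b] ** 2))
    return out


def solve(
    sys: StackedSystem,
    state: dict | None = None,
    X0: np.ndarray | None = None,
) -> np.ndarray:
    """Minimise ||AX - B||_F^2 via sparse normal equations (LSQR fallback).

    Returns X as (J,4,3).  Raises if the normal matrix is numerically
    singular, which for this system means the deformation graph is
    disconnected or degenerate.

    ``state`` is an optional cross-iteration cache: because the sparsity
    pattern of A^T A is fixed for a given source graph (stiffness block
    constant, data/mobility blocks block-diagonal), the LU factor of one
    iteration serves as a near-exact preconditioner for conjugate-gradient
    solves in subsequent iterations, which only perturb the block-diagonal
    values.  Falls back to a fresh factorisation whenever CG stalls.
    """
    AtA = (sys.A.T @ sys.A).tocsc()
    AtB = sys.A.T @ sys.B
    X = None
    if state is not None and state.get("lu") is not None:
        M = LinearOperator(AtA.shape, matvec=state["lu"].solve)
        cols = []
        for k in range(3):
            x0 = None if X0 is None else X0.reshape(-1, 3)[:, k]
            x, info = cg(AtA, AtB[:, k], x0=x0, M=M, rtol=1e-12, atol=0.0,
                         maxiter=100)
            if info != 0:
                cols = None
                break
            cols.append(x)
        if cols is not None:
            X = np.column_stack(cols)
    if X is None:
        try:
            lu = splu(AtA)
            X = lu.solve(AtB)
            if state is not None:
                state["lu"] = lu
        except RuntimeError:
            X = np.column_stack(
                [lsqr(sys.A, sys.B[:, k], atol=1e-12, btol=1e-12)[0]
                 for k in range(3)]
            )
    if not np.all(np.isfinite(X)):
        raise RuntimeError(
            "rank-deficient normal equations: deformation graph is likely "
            "disconnected (prune components before solving)"
        )
    grad = AtA @ X - AtB
    scale = np.max(np.abs(AtB)) or 1.0
    if np.max(np.abs(grad)) > 1e-6 * scale:
        # LU failed silently; refine with LSQR
        X = np.column_stack(
            [lsqr(sys.A, sys.B[:, k], atol=1e-13, btol=1e-13, iter_lim=4 * sys.A.shape[1])[0]
             for k in range(3)]
        )
    return X.reshape(sys.J, 4, 3)


_CORR_FUNCS = {
    "shortest": shortest_distance_correspondences,
    "closest": closest_point_correspondences,
}


def pairwise_nricp(
    source: DeformationGraph,
    target: DeformationGraph,
    alpha: float = 20.0,
    beta: float = 1.0,
    d_max: float = 0.02,
    angle_max_deg: float = 45.0,
    max_iters: int = 10,
    conv_tol: float = 1e-4,
    variant: str = "shortest",
    X0: np.ndarray | None = None,
    log: list | None = None,
    log_context: dict | None = None,
    solver_state: dict | None = None,
) -> np.ndarray:
    """Iterate {correspond -> reject -> assemble -> solve} until converged.

    Stops when ||X - X*||_F between consecutive iterations drops below
    ``conv_tol`` or after ``max_iters`` iterations.  ``source.X`` is updated
    in place to the final estimate.
    """
    if variant not in _CORR_FUNCS:
        raise ValueError(f"unknown correspondence variant {variant!r}")
    source.X = identity_transforms(source.n_nodes) if X0 is None else X0.copy()
    if solver_state is None:
        solver_state = {}
    query = None
    if variant == "shortest":
        query = MeshDistanceQuery(target.warped_nodes(), target.faces)
    for it in range(max_iters):
        if variant == "shortest":
            corrs = shortest_distance_correspondences(source, target, query=query)
        else:
            corrs = closest_point_correspondences(source, target)
        corrs = reject(
            corrs, target, source.warped_normals(),
            d_max=d_max, angle_max_deg=angle_max_deg,
        )
        sys = assemble(source, corrs, alpha=alpha, beta=beta)
        cost_before = system_cost(sys, source.X)
        X_new = solve(sys, state=solver_state, X0=source.X)
        cost_after = system_cost(sys, X_new)
        if cost_after["total"] > cost_before["total"] * (1 + 1e-9) + 1e-15:
            raise AssertionError(
                "closed-form solve increased the fixed-correspondence cost"
            )
        delta = float(np.linalg.norm(X_new - source.X))
        source.X = X_new
        if log is not None:
            entry = {
                "iteration": it,
                "accepted": sys.n_data,
                "rejected": source.n_nodes - sys.n_data,
                "cost_before": cost_before["total"],
                "cost_after": cost_after["total"],
                "cost_data": cost_after.get("data", 0.0),
                "cost_stiffness": cost_after.get("stiffness", 0.0),
                "cost_mobility": cost_after.get("mobility", 0.0),
                "delta_X": delta,
            }
            if log_context:
                entry.update(log_context)
            log.append(entry)
        if delta < conv_tol:
            break
    return source.X


# ---------------------------------------------------------------------------
# multi-view schedule


@dataclass
class Bundle:
    """Ten consecutive frames registered to the first, pooled into one graph."""

    frame_indices: list
    frame_graphs: list  # per-frame graphs; .X maps each into bundle space
    graph: DeformationGraph  # resampled union; .X is the bundle transform


@dataclass
class BundleSet:
    bundles: list

    @property
    def n_frames(self) -> int:
        return sum(len(b.frame_indices) for b in self.bundles)


def _resample_graph(points, normals, cell, radius, mode="auto") -> DeformationGraph:
    return build_graph(points, normals, cell=cell, radius=radius, mode=mode)


def bundle_fit(
    graphs: list,
    bundle_size: int = 10,
    cell: float = 0.006,
    tri_radius: float = 0.025,
    variant: str = "shortest",
    log: list | None = None,
    **nricp_kw,
) -> BundleSet:
    """Local phase: register frames 2..10 of each bundle to its first frame.

    Consecutive frames are warm-started from the previous frame's estimate.
    The bundle graph is the voxel-resampled union of the aligned member
    graphs.  When the frame count is not divisible by ``bundle_size`` the
    remainder forms a smaller final bundle.
    """
    bundles = []
    for start in range(0, len(graphs), bundle_size):
        chunk = list(range(start, min(start + bundle_size, len(graphs))))
        first = graphs[chunk[0]]
        first.X = identity_transforms(first.n_nodes)
        prev_X = None
        for f in chunk[1:]:
            g = graphs[f]
            X0 = None
            if prev_X is not None and len(prev_X) == g.n_nodes:
                X0 = prev_X
            pairwise_nricp(
                g, first, variant=variant, X0=X0, log=log,
                log_context={"phase": "bundle", "bundle": len(bundles), "frame": f},
                **nricp_kw,
            )
            prev_X = g.X
        pts = np.vstack([graphs[f].warped_nodes() for f in chunk])
        nrm = np.vstack([graphs[f].warped_normals() for f in chunk])
        bgraph = _resample_graph(pts, nrm, cell, tri_radius)
        bundles.append(
            Bundle(frame_indices=chunk, frame_graphs=[graphs[f] for f in chunk],
                   graph=bgraph)
        )
    return BundleSet(bundles)


def global_fit(
    bundleset: BundleSet,
    max_steps: int = 100,
    cell: float = 0.006,
    tri_radius: float = 0.025,
    variant: str = "shortest",
    cycle_tol: float | None = 1e-4,
    log: list | None = None,
    **nricp_kw,
) -> BundleSet:
    """Global phase: circularly align each bundle to the union of the others.

    One step = one bundle aligned (<= 10 ICP iterations) against the
    uniform-density resampled union of all other bundles' current node sets.
    Terminates after ``max_steps`` steps, or earlier when the accumulated
    ||delta X~||_F over a full cycle drops below ``cycle_tol`` (set to None to
    always run the full step budget).
    """
    B = len(bundleset.bundles)
    if B < 2:
        return bundleset
    step = 0
    solver_states = [{} for _ in range(B)]  # AtA pattern is fixed per bundle
    while step < max_steps:
        cycle_delta = 0.0
        for b in range(B):
            if step >= max_steps:
                break
            bundle = bundleset.bundles[b]
            others = [bundleset.bundles[o] for o in range(B) if o != b]
            pts = np.vstack([o.graph.warped_nodes() for o in others])
            nrm = np.vstack([o.graph.warped_normals() for o in others])
            target = _resample_graph(pts, nrm, cell, tri_radius)
            X_prev = bundle.graph.X.copy()
            pairwise_nricp(
                bundle.graph, target, variant=variant, X0=X_prev, log=log,
                log_context={"phase": "global", "step": step, "bundle": b},
                solver_state=solver_states[b],
                **nricp_kw,
            )
            cycle_delta += float(np.linalg.norm(bundle.graph.X - X_prev))
            step += 1
        if cycle_tol is not None and cycle_delta < cycle_tol:
            break
    return bundleset
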