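"""End-to-end reconstruction driver and evaluation helpers.

Wires the stages together: preprocessing -> per-frame deformation graphs ->
bundle (local) nonrigid alignment -> global circular refinement -> two-step
warp propagation to the full-resolution clouds -> fusion, smoothing,
resampling, implicit meshing and colour reintegration.  A ``variant`` switch
selects shortest-distance or closest-point correspondences, or a rigid-only
baseline that skips the nonrigid phases entirely.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .camera import CameraIntrinsics, RigidTransform
from .correspond import MeshDistanceQuery
from .fuse import (
    FusedCloud,
    TorsoModel,
    fuse_clouds,
    grid_resample,
    mls_smooth,
    poisson_mesh,
    reintegrate_color,
    reorient_normals,
)
from .graphs import build_graph, estimate_normals, identity_transforms
from .nricp import BundleSet, bundle_fit, global_fit
from .preprocess import backproject, foreground_mask, register_color
from .validation import landmark_error, landmark_position
from .warpfield import WarpField

__all__ = [
    "PipelineConfig",
    "ReconstructionResult",
    "preprocess_frames",
    "reconstruct",
    "evaluate_landmarks",
    "mean_surface_distance",
]


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline (lengths in metres)."""

    graph_voxel: float = 0.006
    tri_radius: float = 0.025
    tri_mu: float = 2.5  # retained for config compatibility with the greedy mesher
    d_max: float = 0.02
    angle_max_deg: float = 45.0
    alpha: float = 20.0
    beta: float = 1.0
    bundle_size: int = 10
    max_steps: int = 100
    max_iters: int = 10
    conv_tol: float = 1e-4
    global_cycle_tol: float | None = 1e-4
    mls_radius: float = 0.008
    resample_cell: float = 0.001
    poisson_depth: int = 9
    poisson_min_samples: int = 10
    poisson_clip: float = 0.005
    color_radius: float = 0.003
    m_nearest: int = 4
    fg_margin: float = 0.15
    variant: str = "shortest"

    def __post_init__(self):
        for name in ("graph_voxel", "tri_radius", "d_max", "mls_radius",
                     "resample_cell", "color_radius", "fg_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.angle_max_deg < 180):
            raise ValueError("angle_max_deg must be in (0, 180)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ReconstructionResult:
    model: TorsoModel | None
    clouds_world: list  # per-frame full-resolution clouds in world coords
    graphs: list  # per-frame deformation graphs (X from the bundle phase)
    bundles: BundleSet | None
    warps: list  # per-frame composed warp callables (identity for rigid)
    normal_warps: list  # per-frame normal-warp callables
    log: pd.DataFrame
    config: PipelineConfig

    def manifest(self, seed=None) -> dict:
        import swayrecon

        return {
            "config": self.config.to_dict(),
            "config_digest": self.config.digest(),
            "seed": seed,
            "n_frames": len(self.clouds_world),
            "version": swayrecon.__version__,
        }


def preprocess_frames(frames, poses, intr_d, intr_rgb=None, T_d2rgb=None,
                      config: PipelineConfig | None = None):
    """Masked, colored, normal-equipped world-frame clouds per frame.

    ``poses`` are world-to-camera; clouds are mapped into the shared world
    frame by the inverse pose so that all later alignment happens in one
    coordinate system.
    """
    config = config or PipelineConfig()
    clouds = []
    for i, (frame, pose) in enumerate(zip(frames, poses)):
        if frame.mask is None:
            frame.mask = foreground_mask(frame.depth, margin=config.fg_margin)
        cloud = backproject(frame, intr_d)
        cloud.frame_index = i
        cloud = estimate_normals(frame, intr_d, cloud)
        if intr_rgb is not None and frame.color is not None:
            cloud = register_color(
                cloud, T_d2rgb or RigidTransform.identity(), intr_rgb, frame.color
            )
        c2w = pose.inverse()
        cloud.points = c2w.apply(cloud.points)
        cloud.normals = cloud.normals @ c2w.R.T
        clouds.append(cloud)
    return clouds


def _compose_warp(frame_field: WarpField, bundle_field: WarpField):
    def warp(pts):
        return bundle_field.warp(frame_field.warp(pts))

    def warp_n(pts, normals):
        mid = frame_field.warp(pts)
        n_mid = frame_field.warp_normals(pts, normals)
        return bundle_field.warp_normals(mid, n_mid)

    return warp, warp_n


def reconstruct(
    frames,
    poses,
    intr_d: CameraIntrinsics,
    intr_rgb: CameraIntrinsics | None = None,
    T_d2rgb: RigidTransform | None = None,
    config: PipelineConfig | None = None,
    variant: str | None = None,
    mesh: bool = True,
) -> ReconstructionResult:
    """Run the full pipeline on an RGBD sequence with given rigid poses.

    ``variant``: "shortest" (default), "closest", or "rigid" (skip the
    nonrigid phases).  ``mesh=False`` stops after fusion and resampling,
    returning a point-set model only — useful when only alignment quality is
    being evaluated.
    """
    config = config or PipelineConfig()
    variant = variant or config.variant
    log: list = []

    clouds = preprocess_frames(frames, poses, intr_d, intr_rgb, T_d2rgb, config)
    graphs = [
        build_graph(c.points, c.normals, cell=config.graph_voxel,
                    radius=config.tri_radius)
        for c in clouds
    ]

    bundles = None
    warps, normal_warps = [], []
    if variant == "rigid":
        ident = lambda pts: np.asarray(pts, dtype=float)  # noqa: E731
        ident_n = lambda pts, normals: np.asarray(normals, dtype=float)  # noqa: E731
        warps = [ident] * len(frames)
        normal_warps = [ident_n] * len(frames)
    else:
        nricp_kw = dict(
            alpha=config.alpha, beta=config.beta, d_max=config.d_max,
            angle_max_deg=config.angle_max_deg, max_iters=config.max_iters,
            conv_tol=config.conv_tol,
        )
        bundles = bundle_fit(
            graphs, bundle_size=config.bundle_size, cell=config.graph_voxel,
            tri_radius=config.tri_radius, variant=variant, log=log, **nricp_kw,
        )
        bundles = global_fit(
            bundles, max_steps=config.max_steps, cell=config.graph_voxel,
            tri_radius=config.tri_radius, variant=variant,
            cycle_tol=config.global_cycle_tol, log=log, **nricp_kw,
        )
        for bundle in bundles.bundles:
            bundle_field = WarpField.from_graph(bundle.graph, config.m_nearest)
            for graph in bundle.frame_graphs:
                frame_field = WarpField.from_graph(graph, config.m_nearest)
                w, wn = _compose_warp(frame_field, bundle_field)
                warps.append(w)
                normal_warps.append(wn)

    warped = []
    for cloud, w, wn in zip(clouds, warps, normal_warps):
        c = FusedCloud(
            points=w(cloud.points),
            normals=wn(cloud.points, cloud.normals),
            colors=cloud.colors,
            frame_ids=np.full(len(cloud), cloud.frame_index),
        )
        warped.append(c)
    fused = fuse_clouds(warped)

    pts, nrm, _ = mls_smooth(fused.points, fused.normals, radius=config.mls_radius)
    nrm = reorient_normals(pts, nrm)
    if fused.colors is not None:
        pts_r, nrm_r, col_r = grid_resample(
            pts, config.resample_cell, normals=nrm, colors=fused.colors
        )
    else:
        pts_r, nrm_r = grid_resample(pts, config.resample_cell, normals=nrm)
        col_r = None
    model_points = FusedCloud(pts_r, nrm_r, col_r)

    model = None
    if mesh:
        clipped, watertight = poisson_mesh(
            pts_r, nrm_r, depth=config.poisson_depth,
            min_samples=config.poisson_min_samples, clip_dist=config.poisson_clip,
        )
        if col_r is not None:
            clipped = reintegrate_color(clipped, pts_r, col_r, radius=config.color_radius)
        model = TorsoModel(points=model_points, mesh=clipped, watertight_mesh=watertight)
    else:
        model = TorsoModel(points=model_points, mesh=None, watertight_mesh=None)

    return ReconstructionResult(
        model=model,
        clouds_world=clouds,
        graphs=graphs,
        bundles=bundles,
        warps=warps,
        normal_warps=normal_warps,
        log=pd.DataFrame(log),
        config=config,
    )


def evaluate_landmarks(
    landmarks_px: pd.DataFrame,
    frames,
    poses,
    intr_d: CameraIntrinsics,
    warps=None,
) -> float:
    """Landmark-spread error of a sequence under per-frame warps.

    Each annotated landmark pixel is backprojected through its frame's depth,
    mapped camera->world by the inverse pose, and pushed through the frame's
    nonrigid warp (identity when ``warps`` is None).  Returns the mean
    Frobenius norm of per-landmark covariances in m^2.
    """
    samples: dict = {}
    for row in landmarks_px.itertuples(index=False):
        j = int(row.frame_id)
        depth = float(frames[j].depth[int(row.y_px), int(row.x_px)])
        warp = warps[j] if warps is not None else None
        pos = landmark_position(
            (float(row.x_px), float(row.y_px)), depth, intr_d, poses[j], warp
        )
        if pos is None:
            continue
        samples.setdefault(int(row.landmark_id), []).append(pos)
    return landmark_error({k: np.array(v) for k, v in samples.items()})


def mean_surface_distance(points: np.ndarray, mesh) -> float:
    """Mean shortest distance from points to a reference mesh surface (m)."""
    query = MeshDistanceQuery(np.asarray(mesh.vertices), np.asarray(mesh.faces))
    _, dist, _, _, _, _ = query.query(np.asarray(points, dtype=float))
    return float(dist.mean())
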