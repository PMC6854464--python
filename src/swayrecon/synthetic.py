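"""Synthetic RGBD fixtures with ground truth.

Emulates the clinical capture setup at desk scale: a subject stands ~0.9 m
from a fixed RGBD camera in front of a background wall at ~2 m and performs a
180° self-rotation — modelled equivalently as a camera arc around a static
subject.  The subject is a parametric torso (elliptic-cylinder trunk, two
breast bumps, a navel dimple) with a smooth skin texture carrying salient
colour spots that double as landmark features.  Postural sway is a smooth
time warp: a sinusoidal breathing displacement along the chest normals plus a
low-frequency global lean, identity at t=0.  Depth is rendered by z-buffer
rasterisation with additive Gaussian noise and 1 mm quantisation; rigid poses
are exact, optionally perturbed to emulate upstream SLAM error.

All randomness flows from a single seed; a fixture is reproducible from
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh
from numba import njit

from .camera import CameraIntrinsics, RigidTransform
from .preprocess import RGBDFrame

__all__ = ["SceneParams", "SyntheticScene", "SyntheticSequence",
           "make_torso", "render_rgbd", "make_sequence"]


@dataclass(frozen=True)
class SceneParams:
    """Study conditions of the synthetic capture."""

    # torso geometry (metres)
    trunk_a: float = 0.17  # lateral semi-axis
    trunk_b: float = 0.11  # anterior-posterior semi-axis
    trunk_height: float = 0.55
    breast_radius: float = 0.05
    breast_theta_deg: float = 22.0  # angular offset of each breast from the midline
    breast_z: float = 0.08
    navel_depth: float = 0.008
    n_theta: int = 160
    n_z: int = 120
    # texture / landmarks
    n_landmarks: int = 12
    spot_radius: float = 0.009
    # sway (metres / Hz); identity at t = 0
    breathing_amp: float = 0.005
    breathing_freq: float = 0.25
    lean_amp: float = 0.005  # displacement at the torso top
    lean_freq: float = 0.08
    # capture
    n_frames: int = 30
    camera_distance: float = 0.9
    sweep_deg: float = 180.0
    frame_dt: float = 1.2
    width: int = 320
    height: int = 240
    focal: float = 288.0
    rgb_baseline: float = 0.025  # depth->RGB sensor offset along camera x
    depth_sigma: float = 0.002
    depth_quant: float = 0.001
    background_depth: float = 2.0
    pose_rot_jitter_deg: float = 0.5
    pose_trans_jitter: float = 0.003


@dataclass
class SyntheticScene:
    params: SceneParams
    mesh: trimesh.Trimesh  # torso at rest (t=0), closed, vertex-colored
    vertex_theta: np.ndarray  # (V,) cylinder angle per vertex (caps: nan)
    vertex_colors: np.ndarray  # (V,3) floats in [0,1]
    breathing_env: np.ndarray  # (V,) smooth chest-region envelope
    landmark_vertices: np.ndarray  # (K,) vertex index of each landmark spot
    torso_landmarks: dict  # named 3D points for volumetry

    def sway_vertices(self, t: float) -> np.ndarray:
        """Vertex positions of the swayed torso at time t (identity at 0)."""
        p = self.params
        v = self.mesh.vertices.copy()
        # breathing along vertex normals, chest region only
        amp = p.breathing_amp * np.sin(2 * np.pi * p.breathing_freq * t)
        v = v + amp * self.breathing_env[:, None] * self.rest_normals
        # global lean: rotation about the lateral (x) axis through the base
        angle = (p.lean_amp / p.trunk_height) * np.sin(2 * np.pi * p.lean_freq * t)
        base = np.array([0.0, 0.0, -p.trunk_height / 2])
        ca, sa = np.cos(angle), np.sin(angle)
        R = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        return (v - base) @ R.T + base

    @property
    def rest_normals(self) -> np.ndarray:
        return np.asarray(self.mesh.vertex_normals)


@dataclass
class SyntheticSequence:
    scene: SyntheticScene
    frames: list  # RGBDFrame per time step
    poses_true: list  # world-to-camera RigidTransform per frame
    poses_input: list  # perturbed poses handed to the pipeline
    intr_d: CameraIntrinsics
    intr_rgb: CameraIntrinsics
    T_d2rgb: RigidTransform
    times: np.ndarray
    landmarks_px: pd.DataFrame  # landmark_id, frame_id, x_px, y_px
    gt_vertices: list  # swayed torso vertices per frame (ground truth)


def _spherical_bump(dist: np.ndarray, radius: float) -> np.ndarray:
    """Height of a spherical cap of the given radius over surface distance."""
    out = np.zeros_like(dist)
    inside = dist < radius
    out[inside] = np.sqrt(radius**2 - dist[inside] ** 2)
    return out


def make_torso(params: SceneParams = SceneParams(), seed: int = 0) -> SyntheticScene:
    """Closed parametric torso mesh with texture spots and landmarks.

    The trunk is an elliptic cylinder (z up, front at +y) displaced along its
    outward normal by two spherical-cap breast bumps and a Gaussian navel
    dimple, capped top and bottom.  ``seed`` controls the landmark spot
    placement and hues.
    """
    p = params
    rng = np.random.default_rng(seed)
    theta = np.linspace(0, 2 * np.pi, p.n_theta, endpoint=False)
    z = np.linspace(-p.trunk_height / 2, p.trunk_height / 2, p.n_z)
    TH, ZZ = np.meshgrid(theta, z, indexing="ij")

    base = np.stack(
        [p.trunk_a * np.cos(TH), p.trunk_b * np.sin(TH), ZZ], axis=-1
    )
    # outward normal of the ellipse cross-section
    nx = p.trunk_b * np.cos(TH)
    ny = p.trunk_a * np.sin(TH)
    nn = np.sqrt(nx**2 + ny**2)
    normal = np.stack([nx / nn, ny / nn, np.zeros_like(TH)], axis=-1)

    def surf_point(th, zz):
        return np.array([p.trunk_a * np.cos(th), p.trunk_b * np.sin(th), zz])

    d_off = np.radians(p.breast_theta_deg)
    centers = [surf_point(np.pi / 2 - d_off, p.breast_z),
               surf_point(np.pi / 2 + d_off, p.breast_z)]
    disp = np.zeros_like(TH)
    flat = base.reshape(-1, 3)
    for c in centers:
        dist = np.linalg.norm(flat - c, axis=1).reshape(TH.shape)
        disp += _spherical_bump(dist, p.breast_radius)
    navel = surf_point(np.pi / 2, -0.12)
    ndist = np.linalg.norm(flat - navel, axis=1).reshape(TH.shape)
    disp -= p.navel_depth * np.exp(-((ndist / 0.015) ** 2))

    verts = (base + disp[..., None] * normal).reshape(-1, 3)

    # faces over the wrapped grid
    i = np.arange(p.n_theta)
    j = np.arange(p.n_z - 1)
    I, J = np.meshgrid(i, j, indexing="ij")
    v00 = I * p.n_z + J
    v01 = I * p.n_z + J + 1
    v10 = ((I + 1) % p.n_theta) * p.n_z + J
    v11 = ((I + 1) % p.n_theta) * p.n_z + J + 1
    faces = np.vstack(
        [
            np.column_stack([v00.ravel(), v10.ravel(), v11.ravel()]),
            np.column_stack([v00.ravel(), v11.ravel(), v01.ravel()]),
        ]
    )
    # caps
    top_center = len(verts)
    bot_center = len(verts) + 1
    verts = np.vstack([verts, [0, 0, p.trunk_height / 2], [0, 0, -p.trunk_height / 2]])
    top_ring = i * p.n_z + (p.n_z - 1)
    bot_ring = i * p.n_z
    top_faces = np.column_stack(
        [top_ring, np.roll(top_ring, -1), np.full(p.n_theta, top_center)]
    )
    bot_faces = np.column_stack(
        [np.roll(bot_ring, -1), bot_ring, np.full(p.n_theta, bot_center)]
    )
    faces = np.vstack([faces, top_faces, bot_faces])

    vertex_theta = np.concatenate([TH.ravel(), [np.nan, np.nan]])
    vertex_z = np.concatenate([ZZ.ravel(), [p.trunk_height / 2, -p.trunk_height / 2]])

    # texture: smooth skin gradient plus salient spots on the visible band
    V = len(verts)
    colors = np.empty((V, 3))
    colors[:, 0] = 0.80 + 0.06 * np.sin(3 * np.nan_to_num(vertex_theta))
    colors[:, 1] = 0.60 + 0.05 * (vertex_z / p.trunk_height)
    colors[:, 2] = 0.50 + 0.04 * np.cos(2 * np.nan_to_num(vertex_theta))
    spot_th = rng.uniform(np.radians(20), np.radians(160), p.n_landmarks)
    spot_z = rng.uniform(-0.20, 0.20, p.n_landmarks)
    hues = rng.permutation(np.linspace(0, 1, p.n_landmarks, endpoint=False))
    from skimage.color import hsv2rgb

    landmark_vertices = np.empty(p.n_landmarks, dtype=np.int64)
    for k in range(p.n_landmarks):
        c = surf_point(spot_th[k], spot_z[k])
        d = np.linalg.norm(verts - c, axis=1)
        landmark_vertices[k] = int(np.argmin(d))
        spot_rgb = hsv2rgb(np.array([[[hues[k], 0.85, 0.75]]]))[0, 0]
        colors[d < p.spot_radius] = spot_rgb

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    # breathing envelope: front-facing, chest-band weighting, zero on caps
    front = np.clip(np.sin(np.nan_to_num(vertex_theta)), 0, None)
    band = np.exp(-(((vertex_z - 0.05) / 0.18) ** 2))
    env = front * band
    env[-2:] = 0.0

    tl = {
        "sternum": surf_point(np.pi / 2, p.breast_z + 0.01),
        "fold_left": surf_point(np.pi / 2 - d_off, p.breast_z - p.breast_radius - 0.015),
        "fold_right": surf_point(np.pi / 2 + d_off, p.breast_z - p.breast_radius - 0.015),
        "axilla_left": surf_point(np.pi / 2 - 2.2 * d_off, p.breast_z + p.breast_radius + 0.01),
        "axilla_right": surf_point(np.pi / 2 + 2.2 * d_off, p.breast_z + p.breast_radius + 0.01),
    }
    return SyntheticScene(
        params=p,
        mesh=mesh,
        vertex_theta=vertex_theta,
        vertex_colors=colors,
        breathing_env=env,
        landmark_vertices=landmark_vertices,
        torso_landmarks=tl,
    )


@njit(cache=True)
def _rasterize(xy, inv_z, cols, faces, H, W, bg_depth):  # pragma: no cover
    depth = np.full((H, W), bg_depth)
    color = np.zeros((H, W, 3))
    zbuf = np.full((H, W), 1.0 / bg_depth)  # stores 1/z; larger = closer
    for f in range(faces.shape[0]):
        i0, i1, i2 = faces[f, 0], faces[f, 1], faces[f, 2]
        if inv_z[i0] <= 0 or inv_z[i1] <= 0 or inv_z[i2] <= 0:
            continue
        x0, y0 = xy[i0, 0], xy[i0, 1]
        x1, y1 = xy[i1, 0], xy[i1, 1]
        x2, y2 = xy[i2, 0], xy[i2, 1]
        xmin = max(int(np.floor(min(x0, x1, x2))), 0)
        xmax = min(int(np.ceil(max(x0, x1, x2))), W - 1)
        ymin = max(int(np.floor(min(y0, y1, y2))), 0)
        ymax = min(int(np.ceil(max(y0, y1, y2))), H - 1)
        if xmin > xmax or ymin > ymax:
            continue
        denom = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        if abs(denom) < 1e-12:
            continue
        for py in range(ymin, ymax + 1):
            for px in range(xmin, xmax + 1):
                w0 = ((y1 - y2) * (px - x2) + (x2 - x1) * (py - y2)) / denom
                w1 = ((y2 - y0) * (px - x2) + (x0 - x2) * (py - y2)) / denom
                w2 = 1.0 - w0 - w1
                if w0 < -1e-9 or w1 < -1e-9 or w2 < -1e-9:
                    continue
                iz = w0 * inv_z[i0] + w1 * inv_z[i1] + w2 * inv_z[i2]
                if iz > zbuf[py, px]:
                    zbuf[py, px] = iz
                    depth[py, px] = 1.0 / iz
                    for c in range(3):
                        color[py, px, c] = (
                            w0 * cols[i0, c] + w1 * cols[i1, c] + w2 * cols[i2, c]
                        )
    return depth, color


def render_rgbd(
    vertices: np.ndarray,
    faces: np.ndarray,
    vertex_colors: np.ndarray,
    pose: RigidTransform,
    intr: CameraIntrinsics,
    noise_sigma: float = 0.002,
    quant: float = 0.001,
    background_depth: float = 2.0,
    rng: np.random.Generator | None = None,
    timestamp: float = 0.0,
) -> RGBDFrame:
    """Z-buffer rasterisation of a colored mesh into an RGBD frame.

    Depth (1/z linear in screen space, so exact per pixel) receives additive
    Gaussian noise and is quantised; pixels not covered by the mesh see the
    background wall.  Same inputs and seed give bit-identical frames.
    """
    rng = rng or np.random.default_rng(0)
    cam = pose.apply(vertices)
    z = cam[:, 2]
    safe_z = np.where(z > 1e-9, z, np.inf)
    xy = cam[:, :2] / safe_z[:, None] * np.array([intr.fx, intr.fy]) + np.array(
        [intr.cx, intr.cy]
    )
    inv_z = np.where(z > 1e-9, 1.0 / safe_z, 0.0)
    depth, color = _rasterize(
        np.ascontiguousarray(xy),
        np.ascontiguousarray(inv_z),
        np.ascontiguousarray(vertex_colors),
        np.ascontiguousarray(faces.astype(np.int64)),
        intr.height,
        intr.width,
        background_depth,
    )
    if noise_sigma > 0:
        depth = depth + rng.normal(0.0, noise_sigma, depth.shape)
    if quant > 0:
        depth = np.round(depth / quant) * quant
    depth = np.maximum(depth, 0.0)
    color8 = (np.clip(color, 0, 1) * 255).astype(np.uint8)
    # uncovered pixels: neutral background colour
    bg = ~np.any(color8 > 0, axis=2)
    color8[bg] = (90, 110, 160)
    return RGBDFrame(depth=depth, color=color8, timestamp=timestamp)


def _lookat_pose(center: np.ndarray, target: np.ndarray) -> RigidTransform:
    """World-to-camera pose of a camera at ``center`` looking at ``target``."""
    f = target - center
    f = f / np.linalg.norm(f)
    up = np.array([0.0, 0.0, 1.0])
    x = np.cross(f, up)
    x = x / np.linalg.norm(x)
    y = np.cross(f, x)
    R_c2w = np.column_stack([x, y, f])
    R = R_c2w.T
    return RigidTransform(R, -R @ center)


def _jitter_pose(pose: RigidTransform, rot_deg: float, trans: float,
                 rng: np.random.Generator) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0, rot_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    dR = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    dt = rng.normal(size=3)
    dt = dt / np.linalg.norm(dt) * rng.uniform(0, trans)
    return RigidTransform(dR @ pose.R, dR @ pose.t + dt)


def make_sequence(
    params: SceneParams = SceneParams(),
    seed: int = 0,
    perturb_poses: bool = True,
) -> SyntheticSequence:
    """Render a full rotating-capture sequence with ground truth.

    Returns frames, exact and (optionally) perturbed world-to-camera poses,
    calibration, per-frame landmark pixel annotations (visibility-tested
    projections of the landmark surface points) and the swayed ground-truth
    vertex positions per frame.
    """
    p = params
    rng = np.random.default_rng(seed)
    scene = make_torso(p, seed=int(rng.integers(2**31 - 1)))
    cy_off = 0.5 if p.height % 2 == 0 else 0.0
    intr_d = CameraIntrinsics(
        fx=p.focal, fy=p.focal, cx=p.width / 2 - cy_off, cy=p.height / 2 - cy_off,
        width=p.width, height=p.height,
    )
    intr_rgb = intr_d
    T_d2rgb = RigidTransform(np.eye(3), np.array([p.rgb_baseline, 0.0, 0.0]))

    phis = np.radians(np.linspace(-p.sweep_deg / 2, p.sweep_deg / 2, p.n_frames))
    times = np.arange(p.n_frames) * p.frame_dt
    target = np.array([0.0, 0.0, 0.0])

    frames, poses_true, poses_input, gt_vertices = [], [], [], []
    lm_rows = []
    for i, (phi, t) in enumerate(zip(phis, times)):
        center = np.array(
            [p.camera_distance * np.sin(phi), p.camera_distance * np.cos(phi), 0.0]
        )
        pose = _lookat_pose(center, target)
        verts = scene.sway_vertices(t)
        gt_vertices.append(verts)
        depth_frame = render_rgbd(
            verts, scene.mesh.faces, scene.vertex_colors, pose, intr_d,
            noise_sigma=p.depth_sigma, quant=p.depth_quant,
            background_depth=p.background_depth, rng=rng, timestamp=t,
        )
        # colour camera sits at a small baseline from the depth sensor
        pose_rgb = T_d2rgb.compose(pose)
        rgb_frame = render_rgbd(
            verts, scene.mesh.faces, scene.vertex_colors, pose_rgb, intr_rgb,
            noise_sigma=0.0, quant=0.0,
            background_depth=p.background_depth, rng=rng, timestamp=t,
        )
        frame = RGBDFrame(depth=depth_frame.depth, color=rgb_frame.color, timestamp=t)
        frames.append(frame)
        poses_true.append(pose)
        poses_input.append(
            _jitter_pose(pose, p.pose_rot_jitter_deg, p.pose_trans_jitter, rng)
            if perturb_poses else pose
        )
        # landmark annotations: project spot centres, test visibility
        lm_world = verts[scene.landmark_vertices]
        lm_cam = pose.apply(lm_world)
        px = intr_d.project(lm_cam)
        for k in range(p.n_landmarks):
            u, v = int(round(px[k, 0])), int(round(px[k, 1]))
            if not (0 <= u < p.width and 0 <= v < p.height) or lm_cam[k, 2] <= 0:
                continue
            if abs(frame.depth[v, u] - lm_cam[k, 2]) > 0.015:
                continue  # occluded (or fell on a noisy background pixel)
            lm_rows.append({"landmark_id": k, "frame_id": i, "x_px": u, "y_px": v})

    landmarks_px = pd.DataFrame(lm_rows, columns=["landmark_id", "frame_id", "x_px", "y_px"])
    return SyntheticSequence(
        scene=scene,
        frames=frames,
        poses_true=poses_true,
        poses_input=poses_input,
        intr_d=intr_d,
        intr_rgb=intr_rgb,
        T_d2rgb=T_d2rgb,
        times=times,
        landmarks_px=landmarks_px,
        gt_vertices=gt_vertices,
    )
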