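"""File formats: depth/colour PNG, calibration YAML, poses/landmarks CSV, PLY.

Depth frames are either 16-bit PNGs in millimetres or 32-bit float arrays in
metres (``.npy``); the dialect is declared in the capture config.  Point
clouds are written as binary little-endian PLY with x,y,z,nx,ny,nz and 8-bit
RGB; meshes go through trimesh.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml
from PIL import Image

from .camera import CameraIntrinsics, RigidTransform

__all__ = [
    "save_depth_png", "load_depth", "save_color_png", "load_color",
    "save_calibration", "load_calibration", "save_poses", "load_poses",
    "write_point_ply", "read_point_ply", "save_graph", "load_graph",
]


def save_depth_png(path, depth_m: np.ndarray) -> None:
    """16-bit PNG in millimetres (the native Kinect-style dialect)."""
    mm = np.clip(np.round(depth_m * 1000.0), 0, 65535).astype(np.uint16)
    Image.fromarray(mm).save(path)


def load_depth(path, dialect: str = "png_mm") -> np.ndarray:
    path = Path(path)
    if dialect == "png_mm" or path.suffix == ".png":
        arr = np.asarray(Image.open(path), dtype=np.float64)
        return arr / 1000.0
    if dialect == "npy_m" or path.suffix == ".npy":
        return np.load(path).astype(np.float64)
    raise ValueError(f"unknown depth dialect {dialect!r}")


def save_color_png(path, color8: np.ndarray) -> None:
    Image.fromarray(color8.astype(np.uint8)).save(path)


def load_color(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def _intr_to_dict(intr: CameraIntrinsics) -> dict:
    return {
        "fx": float(intr.fx), "fy": float(intr.fy),
        "cx": float(intr.cx), "cy": float(intr.cy),
        "width": int(intr.width), "height": int(intr.height),
        "dist": [float(k) for k in intr.dist],
    }


def save_calibration(path, intr_d: CameraIntrinsics, intr_rgb: CameraIntrinsics,
                     T_d2rgb: RigidTransform, depth_dialect: str = "png_mm") -> None:
    data = {
        "depth": _intr_to_dict(intr_d),
        "rgb": _intr_to_dict(intr_rgb),
        "T_depth_to_rgb": T_d2rgb.matrix.tolist(),
        "depth_dialect": depth_dialect,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def load_calibration(path):
    with open(path) as fh:
        data = yaml.safe_load(fh)

    def _intr(d):
        return CameraIntrinsics(
            fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
            width=d["width"], height=d["height"], dist=tuple(d.get("dist", ())),
        )

    return (
        _intr(data["depth"]),
        _intr(data["rgb"]),
        RigidTransform.from_matrix(np.array(data["T_depth_to_rgb"])),
        data.get("depth_dialect", "png_mm"),
    )


def save_poses(path, poses) -> None:
    """World-to-camera poses, one row per frame, 4x4 row-major flattened."""
    rows = []
    for i, p in enumerate(poses):
        rows.append({"frame_id": i, **{f"m{r}{c}": p.matrix[r, c]
                                       for r in range(4) for c in range(4)}})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_poses(path):
    df = pd.read_csv(path)
    poses = []
    for _, row in df.sort_values("frame_id").iterrows():
        M = np.array([[row[f"m{r}{c}"] for c in range(4)] for r in range(4)])
        poses.append(RigidTransform.from_matrix(M))
    return poses


_PLY_HEADER = """ply
format binary_little_endian 1.0
element vertex {n}
property float x
property float y
property float z
property float nx
property float ny
property float nz
property uchar red
property uchar green
property uchar blue
end_header
"""


def write_point_ply(path, points, normals=None, colors=None) -> None:
    points = np.asarray(points, dtype=np.float32)
    n = len(points)
    normals = (np.zeros_like(points) if normals is None
               else np.asarray(normals, dtype=np.float32))
    if colors is None:
        rgb = np.full((n, 3), 200, dtype=np.uint8)
    else:
        colors = np.asarray(colors, dtype=float)
        rgb = (np.clip(colors, 0, 1) * 255).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(_PLY_HEADER.format(n=n).encode("ascii"))
        rec = struct.Struct("<6f3B")
        for i in range(n):
            fh.write(rec.pack(*points[i], *normals[i], *rgb[i]))


def read_point_ply(path):
    with open(path, "rb") as fh:
        header = b""
        while not header.endswith(b"end_header\n"):
            header += fh.readline()
        n = int([ln for ln in header.decode().splitlines()
                 if ln.startswith("element vertex")][0].split()[-1])
        data = np.frombuffer(
            fh.read(), dtype=np.dtype(
                [("xyz", "<f4", 3), ("n", "<f4", 3), ("rgb", "u1", 3)]
            ), count=n,
        )
    return (data["xyz"].astype(float), data["n"].astype(float),
            data["rgb"].astype(float) / 255.0)


def save_graph(path_ply, path_json, graph) -> None:
    """Graph nodes+faces as PLY, per-node 4x3 transforms as sidecar JSON."""
    mesh = trimesh.Trimesh(vertices=graph.nodes, faces=graph.faces, process=False)
    mesh.export(path_ply)
    with open(path_json, "w") as fh:
        json.dump({"X": np.asarray(graph.X).tolist()}, fh)


def load_graph(path_ply, path_json=None):
    from .graphs import DeformationGraph

    mesh = trimesh.load(path_ply, process=False)
    nrm = np.asarray(mesh.vertex_normals)
    X = None
    if path_json is not None and Path(path_json).exists():
        with open(path_json) as fh:
            X = np.array(json.load(fh)["X"])
    return DeformationGraph(
        nodes=np.asarray(mesh.vertices), node_normals=nrm,
        faces=np.asarray(mesh.faces), X=X,
    )
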