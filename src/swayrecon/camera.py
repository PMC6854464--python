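"""Pinhole camera models with radial distortion, and rigid transforms.

Both the structured-light depth sensor and the RGB camera of a Kinect-style
device are modelled as projective pinhole cameras.  Radial lens distortion is
a polynomial in the squared normalised radius; its inverse has no closed form
and is computed iteratively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CameraIntrinsics", "RigidTransform"]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point in pixels.

    ``dist`` holds radial distortion coefficients (k1, k2, ...) applied as
    ``r_d = r_u * (1 + k1 r_u^2 + k2 r_u^4 + ...)`` on normalised image
    coordinates.  Pixel coordinates are 0-based, (u=column, v=row), and depth
    is sampled at the pixel centre.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    dist: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    # -- normalised-coordinate distortion model --------------------------------

    def _distort_norm(self, xn: np.ndarray) -> np.ndarray:
        """Apply the radial polynomial to normalised coordinates (N,2)."""
        if not self.dist:
            return xn
        r2 = np.sum(xn**2, axis=-1, keepdims=True)
        factor = np.ones_like(r2)
        rp = r2.copy()
        for k in self.dist:
            factor = factor + k * rp
            rp = rp * r2
        return xn * factor

    def _undistort_norm(
        self, xd: np.ndarray, tol: float = 1e-10, max_iter: int = 20
    ) -> np.ndarray:
        """Invert the radial polynomial by fixed-point iteration.

        Converges for the mild distortion of consumer depth sensors; tolerance
        is checked on the re-distorted residual.
        """
        if not self.dist:
            return xd
        xn = xd.copy()
        for _ in range(max_iter):
            r2 = np.sum(xn**2, axis=-1, keepdims=True)
            factor = np.ones_like(r2)
            rp = r2.copy()
            for k in self.dist:
                factor = factor + k * rp
                rp = rp * r2
            xn_new = xd / factor
            if np.max(np.abs(self._distort_norm(xn_new) - xd)) < tol:
                xn = xn_new
                break
            xn = xn_new
        return xn

    # -- pixel-level operators -------------------------------------------------

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project camera-frame 3D points (N,3) to distorted pixel coords (N,2)."""
        points = np.asarray(points, dtype=float)
        z = points[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            xn = points[:, :2] / z[:, None]
        xd = self._distort_norm(xn)
        return xd * np.array([self.fx, self.fy]) + np.array([self.cx, self.cy])

    def backproject(self, pixels: np.ndarray, depth: np.ndarray) -> np.ndarray:
        """Backproject distorted pixels (N,2) at metric depth (N,) to (N,3).

        Pixels are undistorted first, so the ray direction corresponds to the
        true (undistorted) viewing geometry; z equals the supplied depth.
        """
        pixels = np.asarray(pixels, dtype=float)
        depth = np.asarray(depth, dtype=float)
        xd = (pixels - np.array([self.cx, self.cy])) / np.array([self.fx, self.fy])
        xn = self._undistort_norm(xd)
        return np.column_stack([xn * depth[:, None], depth])


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t with R in SO(3), t in metres."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("R is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("R is not a proper rotation (det != +1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, T: np.ndarray) -> "RigidTransform":
        T = np.asarray(T, dtype=float)
        return cls(T[:3, :3], T[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.R
        T[:3, 3] = self.t
        return T

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)
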