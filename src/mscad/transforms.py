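"""Rigid and affine spatial transforms in physical (mm) coordinates.

A transform maps points as ``p' = matrix @ p + translation``.  Registration
returns transforms in the resampling convention: they map points of the
*fixed* image's physical space into the *moving* image's physical space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = ["RigidTransform", "AffineTransform", "rotation_matrix"]


def rotation_matrix(angles_deg) -> np.ndarray:
    """Rotation matrix for extrinsic x, y, z rotations (degrees), Rz @ Ry @ Rx."""
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass(frozen=True)
class AffineTransform:
    """Invertible affine map ``p -> matrix @ p + translation``."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.matrix.shape != (3, 3) or self.translation.shape != (3,):
            raise GeometryError("affine transform needs a 3x3 matrix and 3-vector")
        if abs(np.linalg.det(self.matrix)) <= 1e-9:
            raise GeometryError("affine matrix is singular")

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Returns self o other: first apply ``other``, then ``self``."""
        return AffineTransform(
            matrix=self.matrix @ other.matrix,
            translation=self.matrix @ other.translation + self.translation,
        )

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(matrix=inv, translation=-inv @ self.translation)

    @property
    def scales(self) -> np.ndarray:
        """Singular values of the linear part (per-axis scale factors)."""
        return np.linalg.svd(self.matrix, compute_uv=False)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation; rotation orthonormal with determinant +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        r = self.rotation
        if r.shape != (3, 3) or self.translation.shape != (3,):
            raise GeometryError("rigid transform needs a 3x3 rotation and 3-vector")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
            raise GeometryError("rotation matrix is not orthonormal within 1e-6")
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise GeometryError("rotation matrix determinant must be +1")

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    @property
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))

    def as_affine(self) -> AffineTransform:
        return AffineTransform(self.rotation.copy(), self.translation.copy())

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_center(cls, rotation: np.ndarray, translation, center) -> "RigidTransform":
        """Rotation about ``center`` followed by ``translation``."""
        rotation = np.asarray(rotation, dtype=float)
        center = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float) + center - rotation @ center
        return cls(rotation, t)
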