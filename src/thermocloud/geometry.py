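"""Rigid 3D transforms shared by every pipeline stage.

A :class:`RigidTransform` holds a proper rotation ``R`` and a translation
``t`` (metres) and maps points as ``p -> R @ p + t``.  It represents the
board-pose transforms produced during extrinsic calibration (initial PCA
pose, ICP correction, final pose) as well as the camera-from-LiDAR
extrinsics themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform"]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` of 3-space.

    Parameters
    ----------
    R : (3, 3) array_like
        Rotation matrix; must be orthonormal with determinant +1.
    t : (3,) array_like
        Translation in metres.
    """

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("RigidTransform entries must be finite")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("R is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("R is a reflection, not a rotation")
        # re-orthonormalise so downstream compositions stay on SO(3)
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
        if np.linalg.det(R) < 0:  # pragma: no cover - guarded above
            R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    # -- constructors -------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def from_matrix(M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        if M.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return RigidTransform(M[:3, :3], M[:3, 3])

    @staticmethod
    def from_rotvec(rotvec: np.ndarray, t: np.ndarray = (0.0, 0.0, 0.0)) -> "RigidTransform":
        return RigidTransform(Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix(), t)

    # -- algebra ------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.R
        M[:3, 3] = self.t
        return M

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one point or an (N, 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.R.T + self.t

    # -- introspection ------------------------------------------------
    def rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.R).as_rotvec()

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        return float(np.degrees(np.linalg.norm(self.rotvec())))

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.R, np.eye(3), atol=atol) and np.allclose(self.t, 0.0, atol=atol)
        )


def rotation_between(a: RigidTransform, b: RigidTransform) -> float:
    """Angle in degrees between the rotations of two transforms."""
    return RigidTransform(a.R.T @ b.R, np.zeros(3)).rotation_angle_deg()
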