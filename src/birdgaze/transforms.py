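"""Rigid transforms and rotation utilities.

A :class:`Transform` is the proper rigid map ``T_A^B`` taking coordinates
expressed in frame ``A`` to coordinates in frame ``B``::

    x_B = R @ x_A + t

Rotations are stored as proper 3x3 matrices (det = +1).  Interpolation
between rotations follows the geodesic on SO(3) via the axis-angle of the
relative rotation, which avoids quaternion sign ambiguities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Transform",
    "project_to_rotation",
    "chordal_mean_rotation",
    "slerp_rotation",
    "rotation_angle_deg",
]

_ORTHO_TOL = 1e-9


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> None:
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > tol:
        raise ValueError(f"rotation not orthonormal (max deviation {err:.2e})")
    if np.linalg.det(R) < 0:
        raise ValueError("improper rotation (det < 0)")


@dataclass(frozen=True)
class Transform:
    """Proper rigid transform (rotation + translation), metres."""

    rotation: np.ndarray
    translation: np.ndarray
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not self._validated:
            _check_rotation(R)
            if not np.all(np.isfinite(t)):
                raise ValueError("translation not finite")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3), _validated=True)

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0), degrees: bool = False) -> "Transform":
        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float), degrees=degrees).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    @classmethod
    def random(cls, rng: np.random.Generator, translation_scale: float = 1.0) -> "Transform":
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(scale=translation_scale, size=3)
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (…,3) from frame A to frame B."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate free vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "Transform") -> "Transform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return Transform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            _validated=True,
        )

    def __matmul__(self, other: "Transform") -> "Transform":
        return self.compose(other)

    def inverse(self) -> "Transform":
        Rt = self.rotation.T
        return Transform(Rt, -Rt @ self.translation, _validated=True)

    def almost_equal(self, other: "Transform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() <= tol
            and np.abs(self.translation - other.translation).max() <= tol
        )


def project_to_rotation(M: np.ndarray) -> np.ndarray:
    """Nearest proper rotation to ``M`` in the Frobenius norm (SVD projection)."""
    U, _, Vt = np.linalg.svd(np.asarray(M, dtype=float))
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def chordal_mean_rotation(rotations) -> np.ndarray:
    """Chordal mean of a set of rotation matrices.

    The arithmetic mean of the matrices projected back onto SO(3); the
    minimiser of the summed squared Frobenius distance.
    """
    Rs = np.asarray(list(rotations), dtype=float)
    if Rs.size == 0:
        raise ValueError("no rotations to average")
    return project_to_rotation(Rs.mean(axis=0))


def slerp_rotation(R0: np.ndarray, R1: np.ndarray, alpha: float) -> np.ndarray:
    """Geodesic interpolation from R0 (alpha=0) to R1 (alpha=1), shortest path."""
    rel = Rotation.from_matrix(R0.T @ R1).as_rotvec()
    return R0 @ Rotation.from_rotvec(alpha * rel).as_matrix()


def rotation_angle_deg(R0: np.ndarray, R1: np.ndarray | None = None) -> float:
    """Geodesic angle of R0 (or between R0 and R1) in degrees."""
    R = R0 if R1 is None else R0.T @ R1
    return float(np.degrees(np.linalg.norm(Rotation.from_matrix(R).as_rotvec())))
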