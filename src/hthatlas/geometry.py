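"""Rigid-body geometry primitives.

Proper rigid transforms (rotation + translation), least-squares superposition
of point sets under a *fixed* correspondence (the degenerate, single-step case
of constrained iterative closest points), principal-axis fitting and
point-to-line distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R @ x + t``.

    ``rotation`` must be orthonormal with determinant +1 (no reflections);
    this is validated on construction.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite transform")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) not allowed")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


def superpose(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper-rotation superposition of corresponded points.

    Finds the rigid transform minimising ``sum ||T(moving_i) - fixed_i||^2``
    over the given one-to-one correspondence (Kabsch/Wahba problem) and
    returns it with the residual RMSD in the same units as the input.

    Raises ``ValueError`` for fewer than 3 pairs or a degenerate (collinear)
    point set, for which the rotation is not uniquely determined.
    """
    A = np.asarray(moving, dtype=float)
    B = np.asarray(fixed, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    A0 = A - ca
    B0 = B - cb
    # collinearity check: second singular value of either centred cloud ~ 0
    scale = max(np.linalg.norm(A0), 1e-12)
    if np.linalg.svd(A0, compute_uv=False)[1] < 1e-8 * scale:
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(B0, A0)
    R = rot.as_matrix()
    t = cb - R @ ca
    rmsd = float(rssd) / np.sqrt(n)
    return RigidTransform(R, t), rmsd


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between already-corresponded coordinate arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass(frozen=True)
class Line:
    """A 3-D line given by a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            raise ValueError("zero direction vector")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / norm)

    def distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - self.point
        along = rel @ self.direction
        perp = rel - np.outer(along, self.direction)
        return np.linalg.norm(perp, axis=1)


def principal_axis(points: np.ndarray) -> Line:
    """Least-squares line through a point cloud along maximal variance.

    Raises ``ValueError`` when the direction of maximal variance is not
    well separated from the second principal direction being zero with
    fewer than two distinct positions.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points for an axis")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] < 1e-9:
        raise ValueError("degenerate point cloud (all points coincide)")
    return Line(centroid, vt[0])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed proper rotation matrix."""
    return Rotation.random(rng=rng).as_matrix()
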