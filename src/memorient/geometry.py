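"""Geometric kernels: periodic minimum image, angles, Kabsch superposition, RMSD.

All lengths are in nm and all angles in degrees.  Vectors internal to a whole
(unwrapped) molecule are used as-is; only inter-molecular displacements should
be passed through :func:`minimum_image`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["RigidTransform", "minimum_image", "angle_to_normal",
           "kabsch_superpose", "rmsd"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x ↦ R x + t``."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise DomainError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise DomainError("rotation matrix is not proper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def minimum_image(displacement: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vector(s) into the central periodic image.

    Each component of the result lies in ``[-box/2, +box/2)``.  Accepts a
    single 3-vector or an ``(..., 3)`` array.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise DomainError(f"box edge lengths must be positive, got {box}")
    d = np.asarray(displacement, dtype=float)
    return d - box * np.floor(d / box + 0.5)


def angle_to_normal(v: np.ndarray, normal: np.ndarray = (0.0, 0.0, 1.0)
                    ) -> tuple[float, float]:
    """Angle between a vector and the membrane normal.

    Returns ``(theta_degrees, cos_theta)`` with theta in [0, 180].
    """
    v = np.asarray(v, dtype=float)
    n = np.asarray(normal, dtype=float)
    vn = np.linalg.norm(v)
    if vn == 0.0:
        raise DomainError("cannot measure the angle of a zero vector")
    nn = np.linalg.norm(n)
    if nn == 0.0:
        raise DomainError("normal vector must be non-zero")
    c = float(np.clip(np.dot(v, n) / (vn * nn), -1.0, 1.0))
    return float(np.degrees(np.arccos(c))), c


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[RigidTransform, float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``reference``.

    Implements the SVD form of the Kabsch algorithm with the determinant
    correction that excludes reflections.  Returns the transform together
    with the minimised RMSD (nm).

    Requires N >= 3 non-collinear points; degenerate input raises
    :class:`~memorient.errors.DomainError`.
    """
    A = np.asarray(mobile, dtype=float)
    B = np.asarray(reference, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise DomainError("mobile and reference must both be (N, 3)")
    n = A.shape[0]
    if n < 3:
        raise DomainError(f"superposition needs at least 3 points, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(A0, tol=1e-10) < 2:
        raise DomainError("degenerate (collinear) point set")
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    tf = RigidTransform(R, t)
    return tf, rmsd(tf.apply(A), B, superpose=False)


def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation between paired coordinate sets.

    ``sqrt(mean_i |a_i - b_i|^2)`` over the N atom pairs, optionally after
    optimal proper superposition of ``a`` onto ``b``.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise DomainError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.shape[0] < 1:
        raise DomainError("need at least one atom pair")
    if superpose:
        _, value = kabsch_superpose(a, b)
        return value
    d2 = np.sum((a - b) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))
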