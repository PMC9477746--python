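"""Rigid-body and angular geometry primitives.

Centroids, Kabsch superposition, RMSD, signed torsion angles and azimuthal
positions about an axis.  All angles are reported in degrees; all distances
in Angstrom.  The API is purely in-memory: point pairing is given by residue
correspondence upstream, never inferred here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = [
    "RigidTransform",
    "centroid",
    "kabsch_superpose",
    "rmsd",
    "dihedral",
    "vertex_angle",
    "angular_positions",
    "ring_axis",
    "axis_from_points",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` (rotation + translation)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rigid transform needs a 3x3 rotation and a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise GeometryError("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def centroid(points: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of a non-empty point set."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise GeometryError("centroid of an empty point set is undefined")
    return pts.mean(axis=0)


def _as_paired(a, b):
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise GeometryError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    return a, b


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(RigidTransform, rmsd)`` where the transform maps mobile points
    onto the reference frame and the RMSD is the minimised value.  Only proper
    rotations are produced (the reflection branch of the SVD solution is
    folded back by flipping the sign of the smallest singular vector).
    """
    mob, ref = _as_paired(mobile, reference)
    if len(mob) < 3:
        raise GeometryError("superposition needs at least 3 point pairs")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    P = mob - cm
    Q = ref - cr
    # collinear sets leave the rotation under-determined
    for name, X in (("mobile", P), ("reference", Q)):
        if np.linalg.matrix_rank(X, tol=1e-8 * max(1.0, np.abs(X).max())) < 2:
            raise GeometryError(f"{name} point set is collinear; rotation is degenerate")
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    transform = RigidTransform(R, t)
    return transform, rmsd(mob, ref, transform)


def rmsd(a: np.ndarray, b: np.ndarray, transform: RigidTransform | None = None) -> float:
    """Root-mean-square deviation of paired points ``a`` (optionally transformed) vs ``b``."""
    a, b = _as_paired(a, b)
    if transform is not None:
        a = transform.apply(a)
    d = a - b
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle about the p2-p3 axis, IUPAC convention, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for i, b in enumerate((b1, b2, b3), start=1):
        if np.linalg.norm(b) < 1e-9:
            raise GeometryError(f"dihedral: consecutive points {i} and {i + 1} coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("dihedral: three consecutive points are collinear")
    b2u = b2 / np.linalg.norm(b2)
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ b2u)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def vertex_angle(a, vertex, b) -> float:
    """Planar angle at ``vertex`` between directions to ``a`` and ``b``, degrees in [0, 180]."""
    a = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    b = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 or nb < 1e-9:
        raise GeometryError("vertex angle with coincident points is undefined")
    cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _orthonormal_frame(axis_direction: np.ndarray, reference_direction=None):
    u = np.asarray(axis_direction, dtype=float)
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise GeometryError("axis direction must be nonzero")
    u = u / nu
    if reference_direction is None:
        # deterministic choice: the global axis least parallel to u
        cands = np.eye(3)
        reference_direction = cands[int(np.argmin(np.abs(cands @ u)))]
    r = np.asarray(reference_direction, dtype=float)
    e1 = r - (r @ u) * u
    n1 = np.linalg.norm(e1)
    if n1 < 1e-12:
        raise GeometryError("reference direction is parallel to the axis")
    e1 = e1 / n1
    e2 = np.cross(u, e1)
    return u, e1, e2


def angular_positions(
    points: np.ndarray,
    axis_point,
    axis_direction,
    reference_direction=None,
) -> np.ndarray:
    """Azimuth (degrees, in (-180, 180]) of each point about an axis.

    Each point is projected into the plane normal to the axis through
    ``axis_point``; the angle is measured from a fixed reference direction
    (deterministically derived from the axis when not supplied).  A point
    lying on the axis raises an error naming its index.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u, e1, e2 = _orthonormal_frame(axis_direction, reference_direction)
    rel = pts - np.asarray(axis_point, dtype=float)
    x = rel @ e1
    y = rel @ e2
    radial = np.hypot(x, y)
    on_axis = np.where(radial < 1e-8)[0]
    if on_axis.size:
        raise GeometryError(f"point(s) {on_axis.tolist()} lie on the axis; azimuth undefined")
    ang = np.degrees(np.arctan2(y, x))
    ang[ang <= -180.0] += 360.0
    return ang


def ring_axis(points: np.ndarray) -> np.ndarray:
    """Unit normal of a ring-like point set (minimum-variance direction).

    For centroids arranged around a pore this is the pore axis.  The sign is
    arbitrary; callers orient it against a physical direction (DNA exit).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise GeometryError("ring axis needs at least 3 points")
    c = pts - pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(c, full_matrices=False)
    return Vt[-1] / np.linalg.norm(Vt[-1])


def axis_from_points(points: np.ndarray) -> np.ndarray:
    """Unit direction of maximal variance (long axis of an elongated point set)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise GeometryError("axis needs at least 2 points")
    c = pts - pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(c, full_matrices=False)
    return Vt[0] / np.linalg.norm(Vt[0])
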