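"""Vector primitives shared by every interaction rule.

All coordinates are Cartesian and in angstroms; angles are returned in
degrees.  Every routine works on plain length-3 :class:`numpy.ndarray`
objects so the rule evaluators stay free of any molecular data model.

Ring planes are fitted by principal axes (smallest-variance eigenvector of
the member coordinates) rather than a cross product of the first three
atoms, which keeps the normal stable for slightly puckered rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "Plane",
    "RingSystem",
    "GeometryProbe",
    "distance",
    "angle_deg",
    "dihedral_deg",
    "best_fit_plane",
    "ring_center_normal",
    "foot_of_perpendicular",
]

#: members of a ring may deviate from the best-fit plane by at most this
#: much (angstroms) before the ring is rejected as non-planar
DEFAULT_PLANARITY_TOL = 0.35


class GeometryError(ValueError):
    """Degenerate geometric input (coincident points, collinear ring...)."""


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex *b*, in [0, 180] degrees."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("undefined angle: coincident points at vertex")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in (-180, 180] degrees (IUPAC sign)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1  # eclipsed p0/p3 -> 0 deg
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.linalg.norm(b1)
    if n1 == 0.0:
        raise GeometryError("undefined dihedral: zero-length central bond")
    b1u = b1 / n1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    if x == 0.0 and y == 0.0:
        raise GeometryError("undefined dihedral: collinear atoms")
    return float(np.degrees(np.arctan2(y, x)))


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def signed_distance(self, p: np.ndarray) -> float:
        return float(np.dot(np.asarray(p, float) - self.point, self.normal))

    def foot(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, float)
        return p - self.signed_distance(p) * self.normal


def best_fit_plane(points: np.ndarray) -> Plane:
    """Least-squares plane through ``points`` (n x 3), n >= 3.

    The normal is the eigenvector of least coordinate variance; its sign
    is fixed so the first point's cross-product normal has positive
    projection, making the result deterministic.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise GeometryError("plane fit needs at least 3 points in 3-D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # smallest singular vector = direction of least variance
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8:
        raise GeometryError("degenerate plane: points are collinear")
    normal = vt[2]
    ref = np.cross(centered[0], centered[1 % len(centered)])
    if np.dot(normal, ref) < 0:
        normal = -normal
    return Plane(point=centroid, normal=normal / np.linalg.norm(normal))


@dataclass(frozen=True)
class RingSystem:
    """An aromatic ring: member coordinates, centroid and plane.

    ``member_serials`` ties the ring back to atoms of a molecular system
    when available (fixtures build rings from bare coordinates too).
    """

    coords: np.ndarray  # (n, 3)
    member_serials: tuple = ()
    cn: np.ndarray = field(default=None)  # centroid
    plane: Plane = field(default=None)

    @property
    def normal(self) -> np.ndarray:
        return self.plane.normal

    @property
    def radius(self) -> float:
        """Mean centroid-to-member distance d(cn:A)."""
        return float(np.mean(np.linalg.norm(self.coords - self.cn, axis=1)))


def ring_center_normal(
    coords: np.ndarray,
    member_serials: tuple = (),
    planarity_tol: float = DEFAULT_PLANARITY_TOL,
) -> RingSystem:
    """Build a :class:`RingSystem` from >=3 member coordinates.

    Raises :class:`GeometryError` when the members are collinear or the
    ring is not planar.  Planarity is judged leave-one-out: each member
    is measured against the best-fit plane of the *other* members, so a
    single atom puckered 0.5 A out of an otherwise flat ring is caught
    even though it drags the all-member fit toward itself.
    """
    pts = np.asarray(coords, float)
    plane = best_fit_plane(pts)
    worst = 0.0
    if len(pts) >= 4:
        for i in range(len(pts)):
            others = np.delete(pts, i, axis=0)
            worst = max(worst, abs(best_fit_plane(others).signed_distance(pts[i])))
    if worst > planarity_tol:
        raise GeometryError(
            f"ring not planar: max out-of-plane deviation {worst:.3f} A "
            f"exceeds {planarity_tol:.2f} A"
        )
    cn = pts.mean(axis=0)
    return RingSystem(
        coords=pts, member_serials=tuple(member_serials), cn=cn,
        plane=Plane(point=cn, normal=plane.normal),
    )


def foot_of_perpendicular(point: np.ndarray, plane: Plane) -> np.ndarray:
    """Nr: intersection of the perpendicular from ``point`` with ``plane``."""
    return plane.foot(point)


class GeometryProbe(dict):
    """Measured distances (A) and angles (deg) keyed by predicate name.

    A thin dict subclass so hits can carry their measurements without a
    rigid schema; values are plain floats.
    """

    def fmt(self, precision: int = 3) -> str:
        return ";".join(f"{k}={v:.{precision}f}" for k, v in sorted(self.items()))
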