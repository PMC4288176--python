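"""Pure geometry kernel: dihedrals, best-fit planes, superposition, RMSD.

All angles cross this module's boundary in degrees; all lengths in Angstrom.
Every routine accepts array-likes of shape (3,) or (n, 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "Plane",
    "SuperpositionResult",
    "dihedral",
    "best_fit_plane",
    "superpose",
    "rmsd",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric input (coincident/collinear points)."""


@dataclass(frozen=True)
class Plane:
    """Least-squares plane through a point set.

    Attributes
    ----------
    centroid : (3,) ndarray
        Mean of the fitted points, Angstrom.
    normal : (3,) ndarray
        Unit normal. The sign is that of the smallest-eigenvalue
        eigenvector returned by the symmetric eigendecomposition; callers
        that need a particular orientation must re-orient it themselves.
    """

    centroid: np.ndarray
    normal: np.ndarray

    def signed_distance(self, points) -> np.ndarray:
        """Signed distance of points to the plane along the normal."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.centroid) @ self.normal


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper-rotation least-squares fit of one point set onto another.

    ``rotation`` (3x3, det +1) and ``translation`` map mobile coordinates
    onto the reference frame: ``x_fit = x_mobile @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


def _as_vec3(p, name: str) -> np.ndarray:
    v = np.asarray(p, dtype=float).reshape(-1)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise GeometryError(f"{name} must be a finite 3-vector, got {p!r}")
    return v


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Uses the IUPAC convention: looking from p2 toward p3, a clockwise
    rotation of the far bond relative to the near bond is positive.
    Raises :class:`GeometryError` when consecutive points coincide or three
    consecutive points are collinear (the torsion is then undefined).
    """
    a, b, c, d = (_as_vec3(p, f"p{i}") for i, p in enumerate((p1, p2, p3, p4), 1))
    b1, b2, b3 = b - a, c - b, d - c
    for i, v in enumerate((b1, b2, b3), 1):
        if np.linalg.norm(v) < 1e-8:
            raise GeometryError(f"consecutive points {i} and {i + 1} coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        raise GeometryError("three consecutive points are collinear; dihedral undefined")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    ang = np.degrees(np.arctan2(y, x))
    # fold -180 onto +180 so the range is half-open
    if ang <= -180.0 + 1e-12:
        ang += 360.0
    return float(ang)


def best_fit_plane(points) -> Plane:
    """Total-least-squares plane through >= 3 points.

    The normal is the eigenvector of the smallest eigenvalue of the
    covariance of the centered points; collinear input raises
    :class:`GeometryError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("best_fit_plane needs an (n>=3, 3) point array")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    # collinear points: two near-zero eigenvalues -> plane not unique
    if evals[1] <= 1e-10 * max(evals[2], 1.0):
        raise GeometryError("points are collinear; plane is not unique")
    normal = evecs[:, 0]
    normal = normal / np.linalg.norm(normal)
    return Plane(centroid=centroid, normal=normal)


def superpose(mobile, reference) -> SuperpositionResult:
    """Kabsch least-squares superposition of ``mobile`` onto ``reference``.

    Reflections are forbidden (chirality!): the rotation determinant is
    forced to +1 by sign-correcting the smallest singular direction.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise GeometryError(
            f"paired (n, 3) arrays required, got {mob.shape} vs {ref.shape}"
        )
    if mob.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 point pairs")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    h = (mob - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign if sign != 0 else 1.0])
    rot = vt.T @ d @ u.T
    trans = rc - rot @ mc
    fitted = mob @ rot.T + trans
    val = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=val)


def rmsd(a, b, fit: bool = False) -> float:
    """Root-mean-square deviation between paired coordinate sets, Angstrom.

    With ``fit=True`` the deviation is computed after Kabsch superposition.
    """
    pa = np.asarray(a, dtype=float)
    pb = np.asarray(b, dtype=float)
    if pa.shape != pb.shape:
        raise GeometryError(f"paired arrays required, got {pa.shape} vs {pb.shape}")
    if fit:
        return superpose(pa, pb).rmsd
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
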