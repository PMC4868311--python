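"""Exact 3D backbone primitives: dihedral and planar angles, Kabsch superposition.

All angles are reported in degrees. Dihedrals follow the IUPAC biochemical
sign convention (right-handed; trans = +180), computed with the atan2
formulation, which is numerically stable near 0 and 180.
"""

from __future__ import annotations

import numpy as np

# Far below the 1e-3 A coordinate precision of PDB files.
COINCIDENT_TOL = 1e-6


class GeometryError(ValueError):
    """Degenerate geometry: coincident points or collinear central triplet."""


def wrap_degrees(angle: float) -> float:
    """Wrap an angle in degrees onto (-180, 180]."""
    wrapped = -((-angle + 180.0) % 360.0 - 180.0)
    return 180.0 if wrapped == -180.0 else wrapped


def _as_points(*points) -> list[np.ndarray]:
    out = [np.asarray(p, dtype=float) for p in points]
    for p in out:
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise GeometryError(f"expected a finite 3-vector, got {p!r}")
    return out


def dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle (degrees, (-180, 180]) over four points in measurement order.

    The sign is positive for a right-handed (clockwise looking down the
    p1->p2 bond) rotation of the p2->p3 bond relative to p0->p1; a planar
    trans arrangement gives +180, planar cis gives 0.
    """
    a, b, c, d = _as_points(p0, p1, p2, p3)
    for u, v in ((a, b), (b, c), (c, d)):
        if np.linalg.norm(u - v) <= COINCIDENT_TOL:
            raise GeometryError("consecutive points coincide")
    b0 = a - b
    b1 = c - b
    b2 = d - c
    b1n = np.linalg.norm(b1)
    b1 = b1 / b1n
    # reject components along the central bond
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) <= COINCIDENT_TOL or np.linalg.norm(w) <= COINCIDENT_TOL:
        raise GeometryError("collinear triplet: dihedral undefined")
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return wrap_degrees(float(np.degrees(np.arctan2(y, x))))


def planar_angle(a, b, c) -> float:
    """Angle at vertex b in degrees, in [0, 180]."""
    p, q, r = _as_points(a, b, c)
    u = p - q
    v = r - q
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu <= COINCIDENT_TOL or nv <= COINCIDENT_TOL:
        raise GeometryError("coincident points: planar angle undefined")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target`` (Kabsch).

    Parameters
    ----------
    mobile, target:
        (N, 3) arrays of matched coordinates, N >= 3.

    Returns
    -------
    (rmsd, rotation, translation):
        ``rotation`` is a proper rotation (det +1); the transform maps
        ``mobile @ rotation.T + translation`` onto ``target``.
    """
    a = np.asarray(mobile, dtype=float)
    b = np.asarray(target, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise GeometryError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 points")
    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    h = ca.T @ cb
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = ca @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - cb) ** 2, axis=1))))
    translation = b.mean(axis=0) - a.mean(axis=0) @ rot.T
    return rmsd, rot, translation


def superpose_rmsd(a, b) -> float:
    """RMSD in A after optimal rigid superposition of ``a`` onto ``b``."""
    rmsd, _, _ = superpose(a, b)
    return rmsd


def rmsd_no_fit(a, b) -> float:
    """Plain coordinate RMSD without superposition."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise GeometryError(f"coordinate shapes differ: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
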