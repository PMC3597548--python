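"""Rigid-body geometry primitives: dihedrals, internal-coordinate placement,
least-squares superposition and batched RMSD.

All coordinates are in Angstrom, angles in degrees unless stated otherwise.
Torsion angles follow the IUPAC sign convention and are reported in
[-180, 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


class DegenerateGeometryError(ValueError):
    """Raised when a superposition target is under-determined."""


def wrap_angle(angle):
    """Map angles (degrees) into [-180, 180)."""
    return (np.asarray(angle) + 180.0) % 360.0 - 180.0


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in [-180, 180).

    Positive when, looking down the p1->p2 bond, the far bond p2->p3 is
    rotated clockwise from the near bond p1->p0.
    """
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = np.asarray(p0) - np.asarray(p1)
    v = np.asarray(p2) - np.asarray(p1)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def nerf(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d so that |d-c| = bond, angle(d,c,b) = angle and
    dihedral(d,c,b,a) = torsion (degrees).

    Natural extension reference frame (NeRF) construction; the workhorse of
    the internal-coordinate builder.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.radians(angle)
    chi = np.radians(torsion)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def nerf_many(a, b, c, bond: float, angle: float, torsion) -> np.ndarray:
    """Vectorised :func:`nerf` over an array of torsions (frame from fixed
    a, b, c); returns an (n, 3) array."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.radians(angle)
    chi = np.radians(np.asarray(torsion, dtype=float))
    d_local = np.stack(
        [
            np.full_like(chi, -bond * np.cos(theta)),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + d_local @ frame.T


def nerf_batch(a, b, c, bond: float, angle: float, torsion) -> np.ndarray:
    """Fully broadcast :func:`nerf`: a, b, c are (..., 3) arrays (or single
    points) and `torsion` an (...,) array of degrees."""
    torsion = np.asarray(torsion, dtype=float)
    a, b, c = (
        np.broadcast_to(np.asarray(x, dtype=float), torsion.shape + (3,))
        for x in (a, b, c)
    )
    theta = np.radians(angle)
    chi = np.radians(torsion)
    d_local = np.stack(
        [
            np.full_like(chi, -bond * np.cos(theta)),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    frame = np.stack([bc, m, n], axis=-1)  # (..., 3, 3) columns
    return c + np.einsum("...ij,...j->...i", frame, d_local)


def frames_from_points(p1, p2, p3) -> np.ndarray:
    """Right-handed orthonormal frame(s) anchored at p1: e1 along p1->p2,
    e2 in the (p1,p2,p3) plane. Shapes broadcast; returns (..., 3, 3) with
    basis vectors as columns."""
    p1, p2, p3 = (np.asarray(x, dtype=float) for x in (p1, p2, p3))
    e1 = p2 - p1
    e1 = e1 / np.linalg.norm(e1, axis=-1, keepdims=True)
    w = p3 - p1
    w = w - np.sum(w * e1, axis=-1, keepdims=True) * e1
    e2 = w / np.linalg.norm(w, axis=-1, keepdims=True)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=-1)


def rotate_about_axis(coords: np.ndarray, origin, axis, angle_deg: float) -> np.ndarray:
    """Rotate coordinates about the line through `origin` along `axis`."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    origin = np.asarray(origin, dtype=float)
    return rot.apply(coords - origin) + origin


@dataclass(frozen=True)
class Superposition:
    """Optimal proper-rotation least-squares superposition of A onto B.

    ``transform(x) = rotation @ (x - centroid_a) + centroid_b`` minimises the
    RMSD between the transformed anchor atoms of A and the anchors of B.
    """

    rotation: np.ndarray  # (3, 3), det = +1
    centroid_a: np.ndarray
    centroid_b: np.ndarray
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.centroid_a) @ self.rotation.T + self.centroid_b

    @property
    def translation(self) -> np.ndarray:
        return self.centroid_b - self.rotation @ self.centroid_a


def superpose(anchor_a: np.ndarray, anchor_b: np.ndarray) -> Superposition:
    """Least-squares superposition of `anchor_a` onto `anchor_b`.

    Uses the closed-form proper-rotation optimum (reflections excluded).
    Raises :class:`DegenerateGeometryError` for fewer than three points or
    collinear anchors.
    """
    a = np.asarray(anchor_a, dtype=float)
    b = np.asarray(anchor_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"anchor shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - ca, b - cb
    # collinearity check: rank of the centered point cloud
    if np.linalg.matrix_rank(ac, tol=1e-8) < 2:
        raise DegenerateGeometryError("anchor points are collinear")
    rot, rssd = Rotation.align_vectors(bc, ac)
    return Superposition(
        rotation=rot.as_matrix(),
        centroid_a=ca,
        centroid_b=cb,
        rmsd=float(rssd / np.sqrt(a.shape[0])),
    )


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of `a` onto `b` after optimal superposition."""
    return superpose(a, b).rmsd


def kabsch_rmsd_many(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Optimal-superposition RMSD for a batch of coordinate pairs.

    Parameters
    ----------
    a, b : (n_pairs, n_atoms, 3) arrays

    Batched Kabsch via 3x3 SVDs; reflections are excluded by flipping the
    smallest singular value when ``det(U V^T) < 0``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    cov = np.einsum("pij,pik->pjk", ac, bc)
    u, s, vt = np.linalg.svd(cov)
    det = np.linalg.det(np.einsum("pij,pjk->pik", u, vt))
    s_signed = s.copy()
    s_signed[:, -1] *= np.sign(det)
    e0 = np.einsum("pij,pij->p", ac, ac) + np.einsum("pij,pij->p", bc, bc)
    msd = np.maximum(e0 - 2.0 * s_signed.sum(axis=1), 0.0) / n
    return np.sqrt(msd)
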