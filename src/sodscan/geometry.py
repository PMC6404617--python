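"""Low-level 3-D geometry: dihedral angles, internal-coordinate atom
placement (NeRF), and least-squares rigid superposition (Kabsch).

All angles are in degrees; dihedrals lie in (-180, 180]. Distances are in
Angstrom throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "Transform",
    "kabsch_superpose",
    "wrap_angle",
]


class DegenerateGeometryError(ValueError):
    """Raised when points are too few, coincident, or collinear for the
    requested operation."""


def wrap_angle(angle_deg: float) -> float:
    """Map an angle in degrees onto (-180, 180]."""
    a = float(angle_deg) % 360.0
    if a > 180.0:
        a -= 360.0
    # -180 maps to +180 by convention
    if a == -180.0:
        a = 180.0
    return a


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise DegenerateGeometryError(f"zero-length {what}")
    return v / n


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees, in [0, 180]."""
    u = _unit(np.asarray(a, float) - np.asarray(b, float))
    v = _unit(np.asarray(c, float) - np.asarray(b, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180].

    Uses the IUPAC sign convention: looking down the p1->p2 axis, a
    clockwise rotation of p3 relative to p0 is positive.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("dihedral undefined: collinear atoms")
    b1u = _unit(b1)
    m1 = np.cross(n1, b1u)
    x = float(np.dot(n1, n2))
    y = -float(np.dot(m1, n2))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c such that |c-d| = length, angle(b,c,d) =
    angle_deg and dihedral(a,b,c,d) = torsion_deg (NeRF construction)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = _unit(c - b, "b->c bond")
    n = _unit(np.cross(b - a, bc), "a,b,c plane normal (collinear reference atoms?)")
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(tor),
            length * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class Transform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rotation=rt, translation=-rt @ self.translation)

    def compose(self, other: "Transform") -> "Transform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``."""
        return Transform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[Transform, float]:
    """Least-squares superposition of paired coordinate sets.

    Finds the proper rotation R and translation t minimising
    ``sum_i |R m_i + t - r_i|^2`` and returns the transform together with
    the minimised RMSD.

    Parameters
    ----------
    mobile, reference:
        (n, 3) arrays of paired coordinates, n >= 3, not collinear.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matched (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 point pairs")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    mm = mobile - mc
    rr = reference - rc
    # collinearity check: rank of the centred mobile set
    if np.linalg.matrix_rank(mm, tol=1e-8) < 2 or np.linalg.matrix_rank(rr, tol=1e-8) < 2:
        raise DegenerateGeometryError("superposition undefined for collinear point sets")
    h = mm.T @ rr
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    transform = Transform(rotation=rot, translation=trans)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return transform, rmsd
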