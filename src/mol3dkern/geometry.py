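"""Distance-geometry primitives for four consecutive atoms A-B-C-D.

For a bonded chain A-B-C-D the bond angle at B and the torsion (dihedral)
angle between the ABC and BCD planes are both functions of the six pairwise
distances alone.  The bond-angle cosine is the law of cosines,

    cos theta1 = (d_AB^2 + d_BC^2 - d_AC^2) / (2 d_AB d_BC),

and the torsion cosine is the ratio ``U / L`` where, writing
``a = A - B``, ``d = D - C`` and ``u`` for the unit vector along ``B -> C``,

    U = 2 [ a.d - (a.u)(d.u) ],      L = 2 d_AB sin(theta1) d_CD sin(theta2),

with every dot product expressed through the six distances (law of cosines,
polarization identity).  An independent cross-product oracle on the raw
coordinates is provided for validation; the two agree to ~1e-12 on
non-degenerate quadruples.

Note the distance-only torsion yields only ``cos(phi)``: the sign of the
dihedral is not recoverable from distances, so mirror-image (enantiomeric)
quadruples map to identical values.  This is a documented property of the
featurization, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "pairwise_distance",
    "bond_angle_cos",
    "torsion_cos_from_distances",
    "torsion_cos_vector_oracle",
    "QuadrupleGeometry",
]

#: below this denominator the torsion is reported as undefined (collinear triple)
COLLINEAR_TOL = 1e-12
#: cosines within this of [-1, 1] are clamped; farther outside is an error
CLAMP_TOL = 1e-9


def _clamp_cosine(c: float, what: str) -> float:
    if c > 1.0 + CLAMP_TOL or c < -1.0 - CLAMP_TOL:
        raise ValueError(f"{what} = {c!r} is outside [-1, 1]: inconsistent distances")
    return min(1.0, max(-1.0, c))


def pairwise_distance(p, q) -> float:
    """Euclidean distance between two 3D points (Angstrom in, Angstrom out)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.sqrt(((p - q) ** 2).sum()))


def bond_angle_cos(d_ab: float, d_bc: float, d_ac: float) -> float:
    """Cosine of the angle A-B-C from the three pairwise distances.

    Law of cosines at vertex B.  Zero bond lengths are a domain error; values
    within 1e-9 of +/-1 are clamped, values farther outside raise (the three
    distances then violate the triangle inequality).
    """
    if d_ab <= 0 or d_bc <= 0:
        raise ValueError("bond lengths must be positive")
    c = (d_ab * d_ab + d_bc * d_bc - d_ac * d_ac) / (2.0 * d_ab * d_bc)
    return _clamp_cosine(c, "cos(bond angle)")


def _torsion_parts(
    d_ab: float, d_bc: float, d_cd: float, d_ac: float, d_bd: float, d_ad: float
) -> tuple[float, float]:
    """Numerator U and denominator L of the distance-only torsion cosine."""
    # dot products with the B->C axis and between the two bond vectors,
    # all expressed through squared distances
    a_dot_bc = (d_ab**2 + d_bc**2 - d_ac**2) / 2.0  # (A-B).(C-B)
    d_dot_bc = -(d_cd**2 + d_bc**2 - d_bd**2) / 2.0  # (D-C).(C-B)
    a_dot_d = (d_ac**2 + d_bd**2 - d_ad**2 - d_bc**2) / 2.0  # (A-B).(D-C)
    cos_t1 = bond_angle_cos(d_ab, d_bc, d_ac)
    cos_t2 = bond_angle_cos(d_bc, d_cd, d_bd)
    sin2_t1 = max(0.0, 1.0 - cos_t1 * cos_t1)
    sin2_t2 = max(0.0, 1.0 - cos_t2 * cos_t2)
    u = 2.0 * (a_dot_d - a_dot_bc * d_dot_bc / (d_bc * d_bc))
    l = 2.0 * d_ab * math.sqrt(sin2_t1) * d_cd * math.sqrt(sin2_t2)
    return u, l


def torsion_cos_from_distances(
    d_ab: float, d_bc: float, d_cd: float, d_ac: float, d_bd: float, d_ad: float
) -> float | None:
    """Torsion cosine of the chain A-B-C-D from its six pairwise distances.

    Returns ``None`` (torsion undefined) when either atom triple is collinear,
    i.e. the denominator falls below :data:`COLLINEAR_TOL`.  The convention is
    ``cos(phi) = 1`` for a planar cis (eclipsed) quadruple and ``-1`` for trans.
    """
    for d in (d_ab, d_bc, d_cd, d_ac, d_bd, d_ad):
        if d <= 0:
            raise ValueError("all six pairwise distances must be positive")
    u, l = _torsion_parts(d_ab, d_bc, d_cd, d_ac, d_bd, d_ad)
    if l <= COLLINEAR_TOL:
        return None
    return _clamp_cosine(u / l, "cos(torsion)")


def torsion_cos_vector_oracle(p_a, p_b, p_c, p_d) -> float | None:
    """Textbook dihedral cosine from coordinates (cross-product normals).

    Independent of the distance-based route; used as its oracle.  Returns
    ``None`` when either plane is degenerate (collinear triple).
    """
    p_a, p_b, p_c, p_d = (np.asarray(p, dtype=float) for p in (p_a, p_b, p_c, p_d))
    n1 = np.cross(p_b - p_a, p_c - p_b)
    n2 = np.cross(p_c - p_b, p_d - p_c)
    m1 = np.linalg.norm(n1)
    m2 = np.linalg.norm(n2)
    if m1 <= COLLINEAR_TOL or m2 <= COLLINEAR_TOL:
        return None
    return _clamp_cosine(float(n1 @ n2) / (m1 * m2), "cos(torsion)")


@dataclass(frozen=True)
class QuadrupleGeometry:
    """Six pairwise distances of a chain A-B-C-D and the derived angles.

    ``cos_phi`` is ``None`` when the torsion is undefined (collinear triple).
    """

    d_ab: float
    d_bc: float
    d_cd: float
    d_ac: float
    d_bd: float
    d_ad: float
    cos_theta1: float
    cos_theta2: float
    u: float
    l: float
    cos_phi: float | None

    @classmethod
    def from_distances(cls, d_ab, d_bc, d_cd, d_ac, d_bd, d_ad) -> "QuadrupleGeometry":
        cos_t1 = bond_angle_cos(d_ab, d_bc, d_ac)
        cos_t2 = bond_angle_cos(d_bc, d_cd, d_bd)
        u, l = _torsion_parts(d_ab, d_bc, d_cd, d_ac, d_bd, d_ad)
        cos_phi = None if l <= COLLINEAR_TOL else _clamp_cosine(u / l, "cos(torsion)")
        return cls(d_ab, d_bc, d_cd, d_ac, d_bd, d_ad, cos_t1, cos_t2, u, l, cos_phi)

    @classmethod
    def from_points(cls, p_a, p_b, p_c, p_d) -> "QuadrupleGeometry":
        d = pairwise_distance
        return cls.from_distances(
            d(p_a, p_b), d(p_b, p_c), d(p_c, p_d), d(p_a, p_c), d(p_b, p_d), d(p_a, p_d)
        )

    @property
    def distances(self) -> tuple[float, float, float, float, float, float]:
        return (self.d_ab, self.d_bc, self.d_cd, self.d_ac, self.d_bd, self.d_ad)
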