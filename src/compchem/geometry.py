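"""Internal-coordinate geometry: z-matrix to Cartesian conversion and the
distance/angle/dihedral measurements used to check it.

Orientation convention for the emitted Cartesians (the internal coordinates
determine the geometry only up to a rigid motion): atom 1 sits at the
origin, atom 2 on the +z axis, and atom 3 in the xz half-plane with x >= 0.
Dihedral angles follow the IUPAC right-hand-rule sign convention and are
reported in (-180, 180] degrees.
"""

from __future__ import annotations

import math

import numpy as np

from .model import Atom, Molecule, QNameRef, SemanticError, ZMatrix
from .model import CONVENTION_NS

__all__ = [
    "DegenerateGeometryError",
    "zmatrix_to_cartesian",
    "distance",
    "angle",
    "dihedral",
    "cartesian_internal",
]

_MOLECULAR_CONVENTION = QNameRef("convention", "molecular", CONVENTION_NS)


class DegenerateGeometryError(ValueError):
    """Collinear reference atoms make the requested coordinate undefined."""


def distance(a, b) -> float:
    return float(np.linalg.norm(np.asarray(b, float) - np.asarray(a, float)))


def angle(a, b, c) -> float:
    """Included angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("coincident atoms in angle measurement")
    cosang = np.dot(u, v) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def dihedral(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180].

    Positive when, looking from b towards c, the far bond c-d is rotated
    clockwise from the near bond b-a (right-hand rule about b->c).
    """
    p0, p1, p2, p3 = (np.asarray(x, float) for x in (a, b, c, d))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear atoms make the dihedral undefined")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def cartesian_internal(mol: Molecule, *indices: int) -> float:
    """Measure a distance (2 indices), angle (3) or dihedral (4) from a
    Cartesian molecule; indices are zero-based atom positions."""
    if len(set(indices)) != len(indices):
        raise SemanticError("atom indices must be distinct")
    pts = []
    for i in indices:
        if not (0 <= i < len(mol.atoms)):
            raise SemanticError(f"atom index {i} out of range")
        a = mol.atoms[i]
        pts.append((a.x, a.y, a.z))
    if len(pts) == 2:
        return distance(*pts)
    if len(pts) == 3:
        return angle(*pts)
    if len(pts) == 4:
        return dihedral(*pts)
    raise SemanticError("cartesian_internal takes 2, 3 or 4 atom indices")


def _place(
    b: np.ndarray, a: np.ndarray, t: np.ndarray, r: float, theta: float, phi: float
) -> np.ndarray:
    """Position of a new atom at bond length ``r`` from ``b``, bond angle
    ``theta`` (new-b-a) and dihedral ``phi`` (new-b-a-t), angles in degrees."""
    theta = math.radians(theta)
    phi = math.radians(phi)
    u = a - b
    nu = np.linalg.norm(u)
    if nu == 0:
        raise DegenerateGeometryError("bond and angle reference atoms coincide")
    u /= nu
    w = np.cross(t - a, -u)
    nw = np.linalg.norm(w)
    if nw < 1e-10:
        raise DegenerateGeometryError(
            "torsion reference atoms are collinear; dihedral undefined"
        )
    w /= nw
    v = np.cross(w, u)
    d = (
        r * math.cos(theta) * u
        + r * math.sin(theta) * math.cos(phi) * v
        + r * math.sin(theta) * math.sin(phi) * w
    )
    return b + d


def zmatrix_to_cartesian(z: ZMatrix) -> Molecule:
    """Convert a valid z-matrix to Cartesian coordinates (Angstrom).

    Every declared internal coordinate, remeasured from the output, matches
    its input to well below 1e-9; the frame follows the module's orientation
    convention.
    """
    z.validate()
    coords: list[np.ndarray] = []
    for k, row in enumerate(z.rows, start=1):
        if k == 1:
            pos = np.zeros(3)
        elif k == 2:
            pos = coords[row.refs[0] - 1] + np.array([0.0, 0.0, row.length])
        elif k == 3:
            b = coords[row.refs[0] - 1]
            a = coords[row.refs[1] - 1]
            u = a - b
            nu = np.linalg.norm(u)
            if nu == 0:
                raise DegenerateGeometryError("reference atoms coincide")
            u /= nu
            # any direction perpendicular to the 1-2 axis; +x fixes the frame
            v = np.array([1.0, 0.0, 0.0])
            v -= np.dot(v, u) * u
            nv = np.linalg.norm(v)
            if nv < 1e-12:  # axis happens to be +-x; use +y instead
                v = np.array([0.0, 1.0, 0.0])
                v -= np.dot(v, u) * u
                nv = np.linalg.norm(v)
            v /= nv
            theta = math.radians(row.angle)
            pos = b + row.length * (math.cos(theta) * u + math.sin(theta) * v)
        else:
            if row.angle in (0.0, 180.0):
                raise DegenerateGeometryError(
                    f"z-matrix row {k}: bond angle of exactly {row.angle} degrees "
                    "leaves the torsion undefined"
                )
            pos = _place(
                coords[row.refs[0] - 1],
                coords[row.refs[1] - 1],
                coords[row.refs[2] - 1],
                row.length,
                row.angle,
                row.torsion,
            )
        coords.append(pos)
    atoms = [
        Atom(id=f"a{i + 1}", element=row.element, x=float(c[0]), y=float(c[1]), z=float(c[2]))
        for i, (row, c) in enumerate(zip(z.rows, coords))
    ]
    return Molecule(conventionRef=_MOLECULAR_CONVENTION, atoms=atoms)
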