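"""Internal coordinates (bonds, angles, proper torsions) from a bond graph.

The list of internals is derived deterministically from connectivity:
one entry per bond, one per bonded path i–j–k (angle at j), one per
bonded path i–j–k–l of distinct atoms (torsion about j–k). Values are
computed from Cartesian coordinates: distances in Å, angles and
torsions in degrees, torsions wrapped to (−180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Structure

__all__ = [
    "InternalCoordinateList",
    "DegenerateGeometryError",
    "build_internals",
    "bond_length",
    "bond_angle",
    "dihedral",
    "wrap_angle",
]


class DegenerateGeometryError(ValueError):
    """Angle/torsion undefined because of coincident or collinear atoms."""


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle difference in degrees into (−180, 180]."""
    return -np.mod(-np.asarray(deg) + 180.0, 360.0) + 180.0


def bond_length(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[i] - coords[j]))


def bond_angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i–j–k in degrees."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise DegenerateGeometryError(f"angle ({i},{j},{k}): coincident atoms")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed torsion i–j–k–l in degrees, in (−180, 180]."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb2 < 1e-10:
        raise DegenerateGeometryError(f"torsion ({i},{j},{k},{l}): collinear atoms")
    phi = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2)))
    return float(wrap_angle(phi))


@dataclass
class InternalCoordinateList:
    """Typed internal coordinates with current values.

    Entries are ``(i, j, r)``, ``(i, j, k, theta)``, ``(i, j, k, l, phi)``.
    """

    bonds: list[tuple] = field(default_factory=list)
    angles: list[tuple] = field(default_factory=list)
    torsions: list[tuple] = field(default_factory=list)

    def bond_values(self) -> np.ndarray:
        return np.array([e[-1] for e in self.bonds], dtype=float)

    def angle_values(self) -> np.ndarray:
        return np.array([e[-1] for e in self.angles], dtype=float)

    def torsion_values(self) -> np.ndarray:
        return np.array([e[-1] for e in self.torsions], dtype=float)


def build_internals(s: Structure, compute_values: bool = True) -> InternalCoordinateList:
    """Enumerate bonds, angles and torsions of ``s`` and evaluate them.

    Deterministic ordering: bonds sorted as (i, j); angles sorted by
    (j, i, k) with i < k; torsions sorted by (j, k, i, l) with the
    (j, k) bond orientation canonicalized to j < k.
    """
    nbrs: dict[int, list[int]] = {i: [] for i in range(s.n_atoms)}
    for i, j in s.bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    for v in nbrs.values():
        v.sort()

    out = InternalCoordinateList()
    for i, j in sorted(s.bonds):
        r = bond_length(s.coords, i, j) if compute_values else 0.0
        out.bonds.append((i, j, r))

    for j in range(s.n_atoms):
        ns = nbrs[j]
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                i, k = ns[a], ns[b]
                th = bond_angle(s.coords, i, j, k) if compute_values else 0.0
                out.angles.append((i, j, k, th))

    for j, k in sorted(s.bonds):
        for i in nbrs[j]:
            if i == k:
                continue
            for l in nbrs[k]:
                if l == j or l == i:
                    continue
                phi = dihedral(s.coords, i, j, k, l) if compute_values else 0.0
                out.torsions.append((i, j, k, l, phi))
    return out
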