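"""Molecular structures with explicit connectivity.

A :class:`Structure` is the basic carrier of geometry throughout the
package: atoms with element symbols, force-field atom-type labels and
partial charges, Cartesian coordinates in Å, an undirected bond graph,
and (for transition states) one designated *forming bond* — the reaction
coordinate modeled as an ordinary bonded term.

Units repo-wide: Å, degrees, kJ·mol⁻¹, elementary charge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

__all__ = ["Atom", "Structure", "StructureError"]


class StructureError(ValueError):
    """Raised for invalid structures (bad bonds, non-finite coordinates)."""


@dataclass(frozen=True)
class Atom:
    element: str
    atom_type: str
    charge: float = 0.0


@dataclass
class Structure:
    """Atoms + coordinates + bond graph.

    Bond indices are 0-based in memory (file formats use 1-based indices).
    ``forming_bond``, when set, must also appear in ``bonds``.
    """

    atoms: list[Atom]
    coords: np.ndarray
    bonds: list[tuple[int, int]]
    forming_bond: tuple[int, int] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.atoms), 3)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        norm: list[tuple[int, int]] = []
        for i, j in self.bonds:
            i, j = int(i), int(j)
            if i == j:
                raise StructureError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(f"bond ({i},{j}) out of range for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise StructureError(f"duplicate bond {key}")
            seen.add(key)
            norm.append(key)
        self.bonds = norm
        if self.forming_bond is not None:
            i, j = self.forming_bond
            key = (min(int(i), int(j)), max(int(i), int(j)))
            if key not in seen:
                raise StructureError("forming_bond must also be listed in bonds")
            self.forming_bond = key

    # -- convenience -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def atom_types(self) -> list[str]:
        return [a.atom_type for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Copy sharing topology but carrying new coordinates."""
        return replace(
            self,
            coords=np.array(coords, dtype=float),
            bonds=list(self.bonds),
            label=self.label if label is None else label,
        )

    def copy(self) -> "Structure":
        return self.with_coords(self.coords)
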