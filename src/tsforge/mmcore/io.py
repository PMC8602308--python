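"""Structure and force-field file I/O.

* SDF/MOL V2000 (via RDKit): connectivity and coordinates, with package
  conventions carried in SDF property fields — ``TSFF_ATOM_TYPES``
  (space-separated, one per atom), ``TSFF_CHARGES`` (space-separated
  floats, e), ``TSFF_FORMING_BOND`` ("i j", 1-based), optional
  ``TSFF_ENERGY_KJMOL`` on conformer records. Dummy atoms (atomic
  number 0) are exposed as element ``"Du"`` in memory.
* Bare XYZ for geometries (element + coordinates only).
* Force-field files as YAML with sections stretch/bend/torsion/vdw/
  charge/meta; type tuples are comma-joined strings.

All files use Å, degrees, kJ·mol⁻¹ and elementary charge.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import yaml
from rdkit import Chem, RDLogger
from rdkit.Geometry import Point3D

from .forcefield import BendTerm, ForceField, StretchTerm, TorsionTerm, VdwTerm
from .structure import Atom, Structure

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "structure_to_mol",
    "mol_to_structure",
    "write_sdf",
    "read_sdf",
    "write_xyz",
    "read_xyz",
    "forcefield_to_dict",
    "forcefield_from_dict",
    "write_forcefield",
    "read_forcefield",
]

DUMMY_ELEMENT = "Du"


def structure_to_mol(s: Structure, extra_props: dict[str, str] | None = None) -> Chem.Mol:
    """Convert to an RDKit molecule (no sanitization; all bonds single)."""
    mol = Chem.RWMol()
    for a in s.atoms:
        mol.AddAtom(Chem.Atom(0) if a.element == DUMMY_ELEMENT else Chem.Atom(a.element))
    for i, j in s.bonds:
        mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    conf = Chem.Conformer(s.n_atoms)
    for i, xyz in enumerate(s.coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol.AddConformer(conf)
    m = mol.GetMol()
    m.SetProp("_Name", s.label)
    m.SetProp("TSFF_ATOM_TYPES", " ".join(s.atom_types))
    m.SetProp("TSFF_CHARGES", " ".join(f"{a.charge:.6f}" for a in s.atoms))
    if s.forming_bond is not None:
        i, j = s.forming_bond
        m.SetProp("TSFF_FORMING_BOND", f"{i + 1} {j + 1}")
    for k, v in (extra_props or {}).items():
        m.SetProp(k, str(v))
    return m


def mol_to_structure(mol: Chem.Mol) -> tuple[Structure, dict[str, str]]:
    """Convert an RDKit molecule back; returns (structure, sdf properties)."""
    n = mol.GetNumAtoms()
    props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
    types = props.get("TSFF_ATOM_TYPES", "").split() or [
        mol.GetAtomWithIdx(i).GetSymbol() for i in range(n)
    ]
    if len(types) != n:
        raise ValueError("TSFF_ATOM_TYPES length does not match atom count")
    charges = [float(c) for c in props.get("TSFF_CHARGES", "").split()] or [0.0] * n
    if len(charges) != n:
        raise ValueError("TSFF_CHARGES length does not match atom count")
    atoms = []
    for i in range(n):
        at = mol.GetAtomWithIdx(i)
        sym = DUMMY_ELEMENT if at.GetAtomicNum() == 0 else at.GetSymbol()
        atoms.append(Atom(sym, types[i], charges[i]))
    coords = mol.GetConformer().GetPositions()
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    forming = None
    if "TSFF_FORMING_BOND" in props:
        i, j = (int(t) for t in props["TSFF_FORMING_BOND"].split())
        forming = (i - 1, j - 1)
    label = props.get("_Name", mol.GetProp("_Name") if mol.HasProp("_Name") else "")
    return Structure(atoms, coords, bonds, forming_bond=forming, label=label), props


def write_sdf(
    path: str | os.PathLike,
    structures: Iterable[Structure] | Structure,
    extra_props: list[dict[str, str]] | dict[str, str] | None = None,
) -> None:
    if isinstance(structures, Structure):
        structures = [structures]
        if isinstance(extra_props, dict):
            extra_props = [extra_props]
    structures = list(structures)
    if extra_props is None:
        extra_props = [None] * len(structures)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for s, props in zip(structures, extra_props):
            writer.write(structure_to_mol(s, props))
    finally:
        writer.close()


def read_sdf(path: str | os.PathLike) -> list[tuple[Structure, dict[str, str]]]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out = []
    for mol in supplier:
        if mol is None:
            raise ValueError(f"unreadable SDF record in {path}")
        out.append(mol_to_structure(mol))
    return out


# -- XYZ ----------------------------------------------------------------


def write_xyz(path: str | os.PathLike, s: Structure, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"{s.n_atoms}\n{comment if comment is not None else s.label}\n")
        for a, (x, y, z) in zip(s.atoms, s.coords):
            fh.write(f"{a.element} {x:.10f} {y:.10f} {z:.10f}\n")


def read_xyz(path: str | os.PathLike) -> tuple[list[str], np.ndarray, str]:
    """Read a bare XYZ file; returns (elements, coords, comment)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].split()[0])
    comment = lines[1] if len(lines) > 1 else ""
    elements, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return elements, np.array(coords, dtype=float), comment


# -- force-field YAML ----------------------------------------------------


def forcefield_to_dict(ff: ForceField) -> dict:
    return {
        "meta": dict(ff.meta),
        "dielectric": ff.dielectric,
        "stretch": {
            ",".join(k): {"k": t.k, "r0": t.r0} for k, t in sorted(ff.stretch.items())
        },
        "bend": {
            ",".join(k): {"k": t.k, "theta0": t.theta0}
            for k, t in sorted(ff.bend.items())
        },
        "torsion": {
            ",".join(k): {"v1": t.v1, "v2": t.v2, "v3": t.v3}
            for k, t in sorted(ff.torsion.items())
        },
        "vdw": {k: {"eps": t.eps, "rstar": t.rstar} for k, t in sorted(ff.vdw.items())},
        "charge": {k: q for k, q in sorted(ff.charge.items())},
    }


def forcefield_from_dict(data: dict) -> ForceField:
    return ForceField(
        stretch={
            tuple(k.split(",")): StretchTerm(**v)
            for k, v in (data.get("stretch") or {}).items()
        },
        bend={
            tuple(k.split(",")): BendTerm(**v)
            for k, v in (data.get("bend") or {}).items()
        },
        torsion={
            tuple(k.split(",")): TorsionTerm(**v)
            for k, v in (data.get("torsion") or {}).items()
        },
        vdw={k: VdwTerm(**v) for k, v in (data.get("vdw") or {}).items()},
        charge={k: float(v) for k, v in (data.get("charge") or {}).items()},
        dielectric=float(data.get("dielectric", 1.0)),
        meta=dict(data.get("meta") or {}),
    )


def write_forcefield(path: str | os.PathLike, ff: ForceField) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(forcefield_to_dict(ff), fh, sort_keys=False)


def read_forcefield(path: str | os.PathLike) -> ForceField:
    with open(path) as fh:
        return forcefield_from_dict(yaml.safe_load(fh))
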