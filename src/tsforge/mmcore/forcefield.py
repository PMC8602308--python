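"""Force-field parameter containers and keyed parameter access.

The functional form is an MM3-like model: harmonic stretches and bends,
three-term Fourier torsions, exp-6 van der Waals and point-charge
Coulomb electrostatics with a constant dielectric. Parameters are keyed
by atom-type tuples; lookups are symmetric under tuple reversal.

Individual scalar parameters are addressed by string keys of the form
``"stretch/C1,C2/k"`` (section / comma-joined type tuple / field), which
is how the fitting machinery selects its fit vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .structure import Structure

__all__ = [
    "ForceField",
    "MissingParameterError",
    "StretchTerm",
    "BendTerm",
    "TorsionTerm",
    "VdwTerm",
    "COULOMB_K",
]

#: Coulomb constant in kJ·Å·mol⁻¹·e⁻².
COULOMB_K = 1389.35


class MissingParameterError(KeyError):
    """A typed interaction has no parameter record (never a silent zero)."""


@dataclass
class StretchTerm:
    k: float  # kJ·mol⁻¹·Å⁻²
    r0: float  # Å


@dataclass
class BendTerm:
    k: float  # kJ·mol⁻¹·deg⁻²
    theta0: float  # deg


@dataclass
class TorsionTerm:
    v1: float = 0.0  # kJ·mol⁻¹
    v2: float = 0.0
    v3: float = 0.0


@dataclass
class VdwTerm:
    eps: float  # kJ·mol⁻¹
    rstar: float  # Å


_POSITIVE_FIELDS = {
    ("stretch", "k"),
    ("stretch", "r0"),
    ("bend", "k"),
    ("vdw", "eps"),
    ("vdw", "rstar"),
}


@dataclass
class ForceField:
    stretch: dict[tuple[str, str], StretchTerm] = field(default_factory=dict)
    bend: dict[tuple[str, str, str], BendTerm] = field(default_factory=dict)
    torsion: dict[tuple[str, str, str, str], TorsionTerm] = field(default_factory=dict)
    vdw: dict[str, VdwTerm] = field(default_factory=dict)
    charge: dict[str, float] = field(default_factory=dict)
    dielectric: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, t in self.stretch.items():
            if t.k <= 0 or t.r0 <= 0:
                raise ValueError(f"stretch {key}: k and r0 must be > 0")
        for key, t in self.bend.items():
            if t.k <= 0:
                raise ValueError(f"bend {key}: k must be > 0")
        for key, t in self.vdw.items():
            if t.eps <= 0 or t.rstar <= 0:
                raise ValueError(f"vdw {key}: eps and r* must be > 0")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be > 0")

    # -- symmetric lookups -------------------------------------------

    def _lookup(self, table: dict, key: tuple, section: str):
        hit = table.get(key)
        if hit is None:
            hit = table.get(key[::-1])
        if hit is None:
            raise MissingParameterError(f"no {section} parameters for type tuple {key}")
        return hit

    def stretch_for(self, t1: str, t2: str) -> StretchTerm:
        return self._lookup(self.stretch, (t1, t2), "stretch")

    def bend_for(self, t1: str, t2: str, t3: str) -> BendTerm:
        return self._lookup(self.bend, (t1, t2, t3), "bend")

    def torsion_for(self, t1: str, t2: str, t3: str, t4: str) -> TorsionTerm:
        return self._lookup(self.torsion, (t1, t2, t3, t4), "torsion")

    def vdw_for(self, t: str) -> VdwTerm:
        hit = self.vdw.get(t)
        if hit is None:
            raise MissingParameterError(f"no vdw parameters for type {t}")
        return hit

    def charge_for(self, atom_type: str, atom_charge: float | None = None) -> float:
        """Type-level charge record, overriding the per-atom charge if present."""
        if atom_type in self.charge:
            return self.charge[atom_type]
        if atom_charge is not None:
            return atom_charge
        raise MissingParameterError(f"no charge for type {atom_type}")

    def validate_coverage(self, s: Structure) -> None:
        """Raise MissingParameterError unless every term in ``s`` resolves."""
        from .internals import build_internals  # local import avoids cycle

        for a in s.atoms:
            self.vdw_for(a.atom_type)
            self.charge_for(a.atom_type, a.charge)
        tp = s.atom_types
        ic = build_internals(s, compute_values=False)
        for i, j, _ in ic.bonds:
            self.stretch_for(tp[i], tp[j])
        for i, j, k, _ in ic.angles:
            self.bend_for(tp[i], tp[j], tp[k])
        for i, j, k, l, _ in ic.torsions:
            self.torsion_for(tp[i], tp[j], tp[k], tp[l])

    # -- keyed scalar access (the fit vector interface) ---------------

    @staticmethod
    def _split_key(key: str) -> tuple[str, tuple, str]:
        section, types, fld = key.split("/")
        return section, tuple(types.split(",")), fld

    def _record(self, section: str, types: tuple):
        table = getattr(self, section)
        if section in ("vdw", "charge"):
            t = types[0]
            if t not in table:
                raise MissingParameterError(f"no {section} record for {t}")
            return table, t
        if types in table:
            return table, types
        if types[::-1] in table:
            return table, types[::-1]
        raise MissingParameterError(f"no {section} record for {types}")

    def get_param(self, key: str) -> float:
        section, types, fld = self._split_key(key)
        table, k = self._record(section, types)
        rec = table[k]
        return float(rec) if section == "charge" else float(getattr(rec, fld))

    def set_param(self, key: str, value: float) -> None:
        section, types, fld = self._split_key(key)
        if (section, fld) in _POSITIVE_FIELDS and value <= 0:
            raise ValueError(f"{key}: value must be > 0")
        table, k = self._record(section, types)
        if section == "charge":
            table[k] = float(value)
        else:
            setattr(table[k], fld, float(value))

    @staticmethod
    def is_positive_param(key: str) -> bool:
        section, _, fld = ForceField._split_key(key)
        return (section, fld) in _POSITIVE_FIELDS

    def param_keys(self) -> list[str]:
        """All addressable scalar parameter keys, deterministic order."""
        keys: list[str] = []
        for tup in sorted(self.stretch):
            keys += [f"stretch/{','.join(tup)}/{f}" for f in ("k", "r0")]
        for tup in sorted(self.bend):
            keys += [f"bend/{','.join(tup)}/{f}" for f in ("k", "theta0")]
        for tup in sorted(self.torsion):
            keys += [f"torsion/{','.join(tup)}/{f}" for f in ("v1", "v2", "v3")]
        for t in sorted(self.vdw):
            keys += [f"vdw/{t}/eps", f"vdw/{t}/rstar"]
        for t in sorted(self.charge):
            keys.append(f"charge/{t}/q")
        return keys

    def copy(self) -> "ForceField":
        return ForceField(
            stretch={k: replace(v) for k, v in self.stretch.items()},
            bend={k: replace(v) for k, v in self.bend.items()},
            torsion={k: replace(v) for k, v in self.torsion.items()},
            vdw={k: replace(v) for k, v in self.vdw.items()},
            charge=dict(self.charge),
            dielectric=self.dielectric,
            meta=dict(self.meta),
        )

    def effective_charges(self, s: Structure) -> np.ndarray:
        return np.array(
            [self.charge_for(a.atom_type, a.charge) for a in s.atoms], dtype=float
        )
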