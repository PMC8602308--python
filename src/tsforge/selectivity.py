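"""Enantioselectivity from diastereomeric transition-state ensembles.

The two enantiomeric products form through separate families of
transition states (the R pathway and the S pathway). Each family is an
ensemble of conformers; its effective free energy is the Boltzmann sum

    G = −RT ln Σ_i exp(−E_i / RT),

and the selectivity follows from the pathway difference
ΔΔG‡ = G_R − G_S. Sign convention throughout: positive ΔΔG‡ means the
S enantiomer is preferred. The enantiomeric ratio and excess are

    er = exp(ΔΔG‡ / RT),    ee = 100% · (er − 1) / (er + 1),

and the inverse map used for experimental records is
ΔΔG‡ = RT ln(er) with er = (100% + ee) / (100% − ee).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .conformers import SearchOptions, TSEnsemble, mc_search, merge_ensembles
from .mmcore import ForceField, Structure

__all__ = [
    "GAS_CONSTANT",
    "ThermoContext",
    "SelectivityResult",
    "boltzmann_score",
    "ddg_from_ensembles",
    "ddg_to_ee",
    "ee_to_ddg",
    "predict",
]

#: Gas constant in J·mol⁻¹·K⁻¹.
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class ThermoContext:
    """Temperature context for Boltzmann statistics. T in K."""

    T: float = 298.15

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt_kj(self) -> float:
        """RT in kJ·mol⁻¹."""
        return GAS_CONSTANT * self.T / 1000.0


@dataclass
class SelectivityResult:
    ddg: float  # kJ·mol⁻¹, positive => S preferred
    er: float
    ee: float  # %, signed, positive => S
    major: str  # "R" | "S" | "racemic"
    n_conformers: dict[str, int] = field(default_factory=dict)


def boltzmann_score(energies, tc: ThermoContext = ThermoContext()) -> float:
    """Boltzmann-summed effective energy of one ensemble, kJ·mol⁻¹.

    Evaluated via log-sum-exp relative to the minimum, so it is
    overflow-safe and always ≤ min(energies).
    """
    e = np.asarray(list(energies), dtype=float)
    if e.size == 0:
        raise ValueError("empty ensemble")
    rt = tc.rt_kj
    emin = float(e.min())
    return emin - rt * float(logsumexp(-(e - emin) / rt))


def ddg_from_ensembles(
    ens_r: TSEnsemble, ens_s: TSEnsemble, tc: ThermoContext = ThermoContext()
) -> float:
    """ΔΔG‡ = G_R − G_S in kJ·mol⁻¹ (positive ⇒ S preferred)."""
    if not ens_r.conformers or not ens_s.conformers:
        raise ValueError("both pathway ensembles must be nonempty")
    return boltzmann_score(ens_r.energies, tc) - boltzmann_score(ens_s.energies, tc)


def ddg_to_ee(ddg: float, tc: ThermoContext = ThermoContext()) -> tuple[float, float]:
    """(er, signed ee %) from ΔΔG‡; er is for the major pathway, er ≥ 1."""
    if not np.isfinite(ddg):
        raise ValueError("ddg must be finite")
    er = float(np.exp(abs(ddg) * 1000.0 / (GAS_CONSTANT * tc.T)))
    ee = 100.0 * (er - 1.0) / (er + 1.0)
    return er, float(np.copysign(ee, ddg)) if ddg != 0 else 0.0


def ee_to_ddg(ee: float, tc: ThermoContext = ThermoContext()) -> float:
    """Signed ΔΔG‡ (kJ·mol⁻¹) from signed ee (%, positive ⇒ S)."""
    if abs(ee) >= 100.0:
        raise ValueError("|ee| must be < 100%")
    er = (100.0 + ee) / (100.0 - ee)
    return tc.rt_kj * float(np.log(er))


def _result_from_ddg(ddg: float, tc: ThermoContext, n_conf: dict[str, int]) -> SelectivityResult:
    er, ee = ddg_to_ee(ddg, tc)
    if abs(ee) < 1e-9:
        major = "racemic"
    else:
        major = "S" if ddg > 0 else "R"
    return SelectivityResult(ddg=float(ddg), er=er, ee=ee, major=major, n_conformers=n_conf)


def predict(
    ts_structures: list[Structure],
    ff: ForceField,
    opts: SearchOptions,
    tc: ThermoContext = ThermoContext(),
) -> SelectivityResult:
    """Full selectivity prediction for a set of labeled TS structures.

    Each structure's label must end in the product configuration it
    leads to ("..._R" or "..._S", as produced by the assembly module).
    A Monte-Carlo conformational search is run per structure (with a
    per-structure seed derived from ``opts.seed``), the ensembles are
    pooled per configuration, and the pooled Boltzmann sums give ΔΔG‡.
    """
    by_config: dict[str, list[TSEnsemble]] = {"R": [], "S": []}
    for idx, s in enumerate(ts_structures):
        config = s.label.rsplit("_", 1)[-1].upper()
        if config not in ("R", "S"):
            raise ValueError(
                f"structure label {s.label!r} does not end in a product configuration"
            )
        seed = None if opts.seed is None else (opts.seed * 1000 + idx) % (2 ** 31)
        sub = SearchOptions(**{**opts.__dict__, "seed": seed})
        by_config[config].append(mc_search(s, ff, sub))
    if not by_config["R"] or not by_config["S"]:
        raise ValueError("need at least one TS structure per configuration")
    ens_r = merge_ensembles(by_config["R"], label="R")
    ens_s = merge_ensembles(by_config["S"], label="S")
    ddg = ddg_from_ensembles(ens_r, ens_s, tc)
    return _result_from_ddg(
        ddg, tc, {"R": len(ens_r.conformers), "S": len(ens_s.conformers)}
    )
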