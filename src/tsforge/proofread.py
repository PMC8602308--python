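"""Validation against experimental records and stereochemical proofreading.

Experimental enantiomeric excesses are converted to signed ΔΔG‡ values
(positive ⇒ S product) and compared with predictions: the mean unsigned
error (MUE) and the squared Pearson correlation R² quantify agreement.
Records where a *confident* prediction opposes the reported
configuration — both predicted and experimental |ee| at or above a
threshold, with opposite signs — are flagged as suspected literature
misassignments; applying a correction inverts the reported
configuration for the flagged cases. The report carries statistics
before and after correction, on the non-excluded subset (cases tagged
as outside the model's mechanistic regime can be excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .selectivity import ThermoContext, ddg_to_ee, ee_to_ddg

__all__ = [
    "ValidationRecord",
    "ProofreadStats",
    "ProofreadReport",
    "mue",
    "r2",
    "flag_mismatches",
    "apply_corrections",
    "report",
    "records_to_frame",
    "frame_to_records",
    "load_table",
    "save_table",
]

#: ee reported as 100% is clamped here before the (singular) conversion.
EE_CLAMP = 99.9


@dataclass(frozen=True)
class ValidationRecord:
    """One ligand/substrate/nucleophile case.

    ``exp_ee`` is the unsigned experimental ee (%); ``exp_config`` the
    reported configuration of the major product; ``pred_ddg`` the
    predicted ΔΔG‡ in kJ·mol⁻¹ (positive ⇒ S preferred).
    """

    case_id: str
    ligand_id: str
    nucleophile_id: str
    exp_ee: float
    exp_config: str
    pred_ddg: float
    temp_K: float = 298.15
    exclusion_tag: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.exp_ee <= 100.0):
            raise ValueError(f"{self.case_id}: exp_ee must be in [0, 100)")
        if self.exp_config not in ("R", "S"):
            raise ValueError(f"{self.case_id}: exp_config must be 'R' or 'S'")

    @property
    def tc(self) -> ThermoContext:
        return ThermoContext(self.temp_K)

    @property
    def exp_ddg(self) -> float:
        """Signed experimental ΔΔG‡ (kJ·mol⁻¹, positive ⇒ S)."""
        ee = self.exp_ee
        if ee >= EE_CLAMP:
            warnings.warn(
                f"{self.case_id}: ee {ee}% clamped to {EE_CLAMP}% before conversion"
            )
            ee = EE_CLAMP
        signed = ee if self.exp_config == "S" else -ee
        return ee_to_ddg(signed, self.tc)

    @property
    def pred_ee(self) -> float:
        """Signed predicted ee (%) from pred_ddg at the record's T."""
        return ddg_to_ee(self.pred_ddg, self.tc)[1]


def mue(records: list[ValidationRecord]) -> float:
    """Mean unsigned error of predicted vs experimental ΔΔG‡, kJ·mol⁻¹."""
    if not records:
        raise ValueError("no records")
    return float(np.mean([abs(r.pred_ddg - r.exp_ddg) for r in records]))


def r2(records: list[ValidationRecord]) -> float | None:
    """Squared Pearson correlation of predicted vs experimental ΔΔG‡.

    Returns None (undefined) when either side has zero variance or
    fewer than two records are given.
    """
    if len(records) < 2:
        return None
    pred = np.array([r.pred_ddg for r in records])
    exp = np.array([r.exp_ddg for r in records])
    if np.var(pred) == 0 or np.var(exp) == 0:
        return None
    rho = np.corrcoef(pred, exp)[0, 1]
    return float(rho * rho)


def flag_mismatches(
    records: list[ValidationRecord], min_ee: float = 20.0
) -> list[str]:
    """Case ids where a confident prediction opposes the reported sign.

    A record is flagged iff sign(pred ΔΔG‡) ≠ sign(exp ΔΔG‡) and both
    |predicted ee| and the experimental ee are at least ``min_ee``.
    """
    out = []
    for r in records:
        if np.sign(r.pred_ddg) != np.sign(r.exp_ddg) and min(
            abs(r.pred_ee), r.exp_ee
        ) >= min_ee:
            out.append(r.case_id)
    return out


def apply_corrections(
    records: list[ValidationRecord], ids: list[str]
) -> list[ValidationRecord]:
    """Invert the reported configuration for the listed case ids.

    Everything else is untouched; applying the same correction twice
    restores the original records.
    """
    known = {r.case_id for r in records}
    unknown = set(ids) - known
    if unknown:
        raise KeyError(f"unknown case ids: {sorted(unknown)}")
    idset = set(ids)
    return [
        replace(r, exp_config=("S" if r.exp_config == "R" else "R"))
        if r.case_id in idset
        else r
        for r in records
    ]


@dataclass
class ProofreadStats:
    mue: float
    r2: float | None


@dataclass
class ProofreadReport:
    initial: ProofreadStats
    corrected: ProofreadStats
    n_total: int
    n_excluded: int
    n_flagged: int
    flagged_ids: list[str]
    min_ee: float


def report(
    records: list[ValidationRecord],
    exclude_tags: tuple[str, ...] = (),
    min_ee: float = 20.0,
) -> ProofreadReport:
    """Full proofreading pass: statistics, flags and corrected statistics.

    Statistics are computed on the subset whose ``exclusion_tag`` is not
    in ``exclude_tags``; both pre-correction and post-correction MUE/R²
    are reported.
    """
    kept = [r for r in records if r.exclusion_tag not in exclude_tags]
    if not kept:
        raise ValueError("all records excluded")
    flagged = flag_mismatches(kept, min_ee=min_ee)
    corrected = apply_corrections(kept, flagged)
    return ProofreadReport(
        initial=ProofreadStats(mue(kept), r2(kept)),
        corrected=ProofreadStats(mue(corrected), r2(corrected)),
        n_total=len(kept),
        n_excluded=len(records) - len(kept),
        n_flagged=len(flagged),
        flagged_ids=flagged,
        min_ee=min_ee,
    )


# -- CSV interface -------------------------------------------------------

_COLUMNS = [
    "case_id",
    "ligand_id",
    "nucleophile_id",
    "exp_ee_percent",
    "exp_config",
    "pred_ddg_kJmol",
    "temp_K",
    "exclusion_tag",
]


def records_to_frame(records: list[ValidationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "ligand_id": r.ligand_id,
                "nucleophile_id": r.nucleophile_id,
                "exp_ee_percent": r.exp_ee,
                "exp_config": r.exp_config,
                "pred_ddg_kJmol": r.pred_ddg,
                "pred_ee_percent": r.pred_ee,
                "temp_K": r.temp_K,
                "exclusion_tag": r.exclusion_tag,
            }
            for r in records
        ]
    )


def frame_to_records(df: pd.DataFrame) -> list[ValidationRecord]:
    out = []
    for _, row in df.iterrows():
        out.append(
            ValidationRecord(
                case_id=str(row["case_id"]),
                ligand_id=str(row.get("ligand_id", "")),
                nucleophile_id=str(row.get("nucleophile_id", "")),
                exp_ee=float(row["exp_ee_percent"]),
                exp_config=str(row["exp_config"]),
                pred_ddg=float(row["pred_ddg_kJmol"]),
                temp_K=float(row["temp_K"]) if "temp_K" in row and pd.notna(row["temp_K"]) else 298.15,
                exclusion_tag=(
                    str(row["exclusion_tag"])
                    if "exclusion_tag" in row and pd.notna(row["exclusion_tag"])
                    else ""
                ),
            )
        )
    return out


def load_table(path) -> list[ValidationRecord]:
    return frame_to_records(pd.read_csv(path))


def save_table(path, records: list[ValidationRecord]) -> None:
    records_to_frame(records).to_csv(path, index=False)
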