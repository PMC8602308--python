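"""Synthetic fixtures: toy TS systems, mock-QM references, validation tables.

Everything the test suite and the acceptance experiments need is
fabricated here from known ground truth, reproducibly from a seed:

* :func:`make_toy_ts_system` builds a small typed chain with one
  designated forming bond and a complete ground-truth force field, and
  minimizes the geometry under it — a stand-in for a simplified
  transition-state training structure.
* :func:`mock_qm_reference` fabricates reference data from the true
  force field; the Hessian's forming-bond mode eigenvalue is negated in
  place so the reference looks like a first-order saddle and the fitting
  pipeline must exercise the eigenvalue replacement. Because the true
  mode eigenvalue is recorded as the per-structure replacement value,
  the true force field is the exact global optimum of the penalty —
  which is what makes parameter-recovery experiments well-posed.
* :func:`perturb_ff` scrambles parameters for recovery experiments.
* :func:`make_validation_fixture` fabricates a literature-style
  validation table with planted, confidently-wrong configuration
  assignments and optional out-of-scope (mechanism-shift) cases.
* :func:`make_catalysis_fixture` builds mirror-image TS templates with
  an achiral ligand set — the end-to-end chirality null system.

The generators never mimic real quantum-chemical error structure; they
exist so that truth is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import AnchorSite, Fragment, Template, enumerate_ts
from .mmcore import (
    Atom,
    BendTerm,
    ForceField,
    Structure,
    StretchTerm,
    TorsionTerm,
    VdwTerm,
    build_internals,
    hessian,
    minimize,
)
from .mmcore.io import DUMMY_ELEMENT
from .proofread import ValidationRecord
from .q2mm import EPS_NEG, ReferenceStructure
from .selectivity import ThermoContext, ddg_to_ee, ee_to_ddg

__all__ = [
    "ToySpec",
    "make_toy_ts_system",
    "make_three_well_system",
    "mock_qm_reference",
    "perturb_ff",
    "make_validation_fixture",
    "make_catalysis_fixture",
]


@dataclass
class ToySpec:
    """Size/seed recipe for a toy TS chain.

    The topology is a simple chain of ``n_heavy_atoms``; its rotatable
    torsion count is ``n_heavy_atoms − 3`` (terminal bonds and the
    forming bond — which is terminal — are never rotatable). Give either
    field; if both are given they must be consistent.
    """

    n_heavy_atoms: int | None = None
    n_rotatable: int | None = None
    include_forming_bond: bool = True
    charge_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_heavy_atoms is None and self.n_rotatable is None:
            self.n_heavy_atoms = 6
        if self.n_heavy_atoms is None:
            self.n_heavy_atoms = self.n_rotatable + 3
        if self.n_rotatable is None:
            self.n_rotatable = self.n_heavy_atoms - 3
        if self.n_heavy_atoms != self.n_rotatable + 3:
            raise ValueError("inconsistent n_heavy_atoms / n_rotatable")
        if not (4 <= self.n_heavy_atoms <= 20):
            raise ValueError("n_heavy_atoms must be in 4..20")


def _chain_coords(n: int, r0s: np.ndarray, theta0s: np.ndarray, phis: np.ndarray) -> np.ndarray:
    """Place a chain from internal coordinates (lengths Å, angles deg)."""
    coords = np.zeros((n, 3))
    coords[1] = [r0s[0], 0.0, 0.0]
    if n > 2:
        t = np.radians(180.0 - theta0s[0])
        coords[2] = coords[1] + r0s[1] * np.array([np.cos(t), np.sin(t), 0.0])
    for i in range(3, n):
        # NeRF-style placement from the three previous atoms
        a, b, c = coords[i - 3], coords[i - 2], coords[i - 1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        nrm = np.cross(ab, bc)
        nrm /= np.linalg.norm(nrm)
        m = np.cross(nrm, bc)
        r = r0s[i - 1]
        th = np.radians(theta0s[i - 2])
        ph = np.radians(phis[i - 3])
        d = np.array(
            [-r * np.cos(th), r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph)]
        )
        coords[i] = c + d[0] * bc + d[1] * m + d[2] * nrm
    return coords


def make_toy_ts_system(spec: ToySpec) -> tuple[Structure, ForceField]:
    """Toy TS chain + complete ground-truth force field, minimized.

    Atom 0 is a nucleophile-like atom (type NU) attached to atom 1 (the
    attacked carbon, type CT) through the forming bond; the rest of the
    chain cycles through generic carbon types. All parameters are drawn
    from seeded, physically plausible ranges.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_heavy_atoms
    if spec.include_forming_bond:
        types = ["NU", "CT"] + [f"C{(i % 3) + 1}" for i in range(n - 2)]
        elements = ["N"] + ["C"] * (n - 1)
    else:
        types = [f"C{(i % 3) + 1}" for i in range(n)]
        elements = ["C"] * n
    bonds = [(i, i + 1) for i in range(n - 1)]
    forming = (0, 1) if spec.include_forming_bond else None

    # one ground-truth record per distinct type tuple in the chain
    ff = ForceField()
    for i, j in bonds:
        key = (types[i], types[j])
        if key in ff.stretch or key[::-1] in ff.stretch:
            continue
        if forming is not None and (i, j) == forming:
            ff.stretch[key] = StretchTerm(
                k=float(rng.uniform(800, 1200)), r0=float(rng.uniform(1.9, 2.1))
            )
        else:
            ff.stretch[key] = StretchTerm(
                k=float(rng.uniform(1800, 2800)), r0=float(rng.uniform(1.38, 1.56))
            )
    skeleton = Structure(
        [Atom(e, t) for e, t in zip(elements, types)],
        np.arange(n)[:, None] * np.array([1.5, 0.0, 0.0]),
        bonds,
    )
    ic = build_internals(skeleton, compute_values=False)
    for i, j, k, _ in ic.angles:
        key = (types[i], types[j], types[k])
        if key not in ff.bend and key[::-1] not in ff.bend:
            ff.bend[key] = BendTerm(
                k=float(rng.uniform(0.05, 0.12)), theta0=float(rng.uniform(106, 116))
            )
    for i, j, k, l, _ in ic.torsions:
        key = (types[i], types[j], types[k], types[l])
        if key not in ff.torsion and key[::-1] not in ff.torsion:
            ff.torsion[key] = TorsionTerm(
                v1=float(rng.uniform(0, 2.5)),
                v2=float(rng.uniform(0, 1.5)),
                v3=float(rng.uniform(4, 9)),
            )
    for t in dict.fromkeys(types):
        ff.vdw[t] = VdwTerm(
            eps=float(rng.uniform(0.2, 0.5)), rstar=float(rng.uniform(3.6, 4.2))
        )
        ff.charge[t] = float(rng.uniform(-0.15, 0.15) * spec.charge_scale)

    # extended starting geometry from the equilibrium internals
    r0s = np.array([ff.stretch_for(types[i], types[j]).r0 for i, j in bonds])
    theta0s = np.array(
        [ff.bend_for(types[i - 1], types[i], types[i + 1]).theta0 for i in range(1, n - 1)]
    )
    phis = np.array([180.0 if m % 2 == 0 else 65.0 for m in range(max(n - 3, 0))])
    coords = _chain_coords(n, r0s, theta0s, phis)
    atoms = [Atom(e, t, ff.charge[t]) for e, t in zip(elements, types)]
    s0 = Structure(atoms, coords, bonds, forming_bond=forming, label=f"toy_seed{spec.seed}")
    res = minimize(s0, ff, max_steps=5000, grad_tol=1e-6)
    return res.structure, ff


def make_three_well_system() -> tuple[Structure, ForceField]:
    """Deterministic butane-like chain with one three-well torsion.

    Four atoms, one rotatable bond; the torsional potential is dominated
    by a threefold term with a smaller onefold term that splits the anti
    well (global minimum) from the degenerate gauche± pair. Every well
    spans a basin of roughly 120°, so both an exhaustive scan and a short
    stochastic search must find all three minima. No forming bond: this
    fixture isolates the conformational-search machinery.
    """
    types = ["TA", "TB", "TB", "TA"]
    bonds = [(0, 1), (1, 2), (2, 3)]
    ff = ForceField()
    ff.stretch[("TA", "TB")] = StretchTerm(k=2200.0, r0=1.52)
    ff.stretch[("TB", "TB")] = StretchTerm(k=2200.0, r0=1.54)
    ff.bend[("TA", "TB", "TB")] = BendTerm(k=0.08, theta0=112.0)
    ff.torsion[("TA", "TB", "TB", "TA")] = TorsionTerm(v1=1.6, v2=0.0, v3=6.0)
    for t in ("TA", "TB"):
        ff.vdw[t] = VdwTerm(eps=0.3, rstar=3.8)
        ff.charge[t] = 0.0
    coords = _chain_coords(
        4, np.array([1.52, 1.54, 1.52]), np.array([112.0, 112.0]), np.array([180.0])
    )
    atoms = [Atom("C", t) for t in types]
    s0 = Structure(atoms, coords, bonds, label="three_well")
    res = minimize(s0, ff, max_steps=5000, grad_tol=1e-6)
    return res.structure, ff


def mock_qm_reference(
    s: Structure,
    ff_true: ForceField,
    noise_sd: float = 0.0,
    seed: int | None = None,
    ts: bool = True,
) -> ReferenceStructure:
    """Fabricate reference data for ``s`` from the true force field.

    For a TS reference the true-FF Hessian's forming-bond mode
    eigenvalue λ_m is negated (H ← H − 2 λ_m v_m v_mᵀ), emulating the
    single imaginary mode of a first-order saddle, and λ_m is stored as
    the per-structure replacement eigenvalue so eigenvalue replacement
    restores the true Hessian exactly. Optional Gaussian noise (sd in e,
    seeded) is added to the reference charges.
    """
    h = hessian(s, ff_true)
    omega_override = None
    if ts:
        if s.forming_bond is None:
            raise ValueError("TS reference requested but structure has no forming bond")
        i, j = s.forming_bond
        u = s.coords[i] - s.coords[j]
        u /= np.linalg.norm(u)
        t = np.zeros(3 * s.n_atoms)
        t[3 * i : 3 * i + 3] = u
        t[3 * j : 3 * j + 3] = -u
        t /= np.linalg.norm(t)
        w, v = np.linalg.eigh(h)
        m = int(np.argmax(np.abs(v.T @ t)))
        lam_m = float(w[m])
        if lam_m <= EPS_NEG:
            raise ValueError("forming-bond mode eigenvalue is not clearly positive")
        h = h - 2.0 * lam_m * np.outer(v[:, m], v[:, m])
        omega_override = lam_m

    charges = ff_true.effective_charges(s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        charges = charges + rng.normal(0.0, noise_sd, size=charges.shape)

    return ReferenceStructure(
        structure=s.copy(),
        hessian_ref=h,
        charges_ref=charges,
        internals_ref=build_internals(s),
        is_ts=ts,
        omega_override=omega_override,
    )


def perturb_ff(
    ff: ForceField,
    rel_fraction: float,
    seed: int | None = None,
    keys: list[str] | None = None,
) -> ForceField:
    """Multiply selected parameters by (1 + u), u ~ U(−f, +f), seeded.

    With |u| < 1 positivity-constrained parameters stay positive by
    construction. Default: every addressable parameter.
    """
    if not (0 < rel_fraction < 1):
        raise ValueError("rel_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = ff.copy()
    for key in keys if keys is not None else out.param_keys():
        u = float(rng.uniform(-rel_fraction, rel_fraction))
        out.set_param(key, out.get_param(key) * (1.0 + u))
    return out


# ----------------------------------------------------------------------


def make_validation_fixture(
    n: int = 77,
    error_sd_kJmol: float = 2.0,
    mismatch_ids: list[int] | None = None,
    seed: int = 0,
    exclusion_ids: list[int] | None = None,
    exclusion_tag: str = "indphox",
    min_ee: float = 20.0,
) -> list[ValidationRecord]:
    """Literature-style validation table with planted misassignments.

    True ΔΔG‡ values are drawn uniformly on ±12 kJ·mol⁻¹ and define the
    experimental ee and configuration; predictions are the truth plus
    Gaussian noise. For ids in ``mismatch_ids`` (1-based) the recorded
    configuration is INVERTED — a planted literature misassignment; the
    truth for those cases is redrawn until confidently selective, and
    the prediction noise is redrawn until the prediction is itself
    confidently on the true side, so the planted set is exactly the set
    a confident sign-disagreement filter recovers. Non-planted cases
    reject the rare noise draws that would mimic a confident
    misassignment (predictions never confidently flip sign), mirroring
    the scenario the fixture emulates: errors live in the literature
    assignments, not in the model's sign. Ids in ``exclusion_ids`` get
    ``exclusion_tag`` and a large same-sign prediction bias, emulating
    cases outside the model's mechanistic regime.
    """
    mismatch = set(mismatch_ids or [])
    excluded = set(exclusion_ids or [])
    if not mismatch <= set(range(1, n + 1)) or not excluded <= set(range(1, n + 1)):
        raise ValueError("planted ids must be within 1..n")
    rng = np.random.default_rng(seed)
    tc = ThermoContext()
    ee_floor_ddg = ee_to_ddg(min_ee, tc)  # |ΔΔG| at the flagging threshold
    records = []
    for i in range(1, n + 1):
        planted = i in mismatch
        true = float(rng.uniform(-12.0, 12.0))
        if planted:
            while abs(true) < 2.0 * ee_floor_ddg + 1.0:
                true = float(rng.uniform(-12.0, 12.0))
        pred = true
        for _ in range(1000):
            pred = true + float(rng.normal(0.0, error_sd_kJmol))
            same_side = np.sign(pred) == np.sign(true)
            if planted:
                if same_side and abs(pred) >= ee_floor_ddg + 0.3:
                    break
            else:
                confident_flip = (
                    not same_side
                    and abs(pred) >= ee_floor_ddg
                    and abs(true) >= ee_floor_ddg
                )
                if not confident_flip:
                    break
        if i in excluded:
            sign = np.sign(true) if true != 0 else 1.0
            pred = float(sign * rng.uniform(8.0, 12.0))
        exp_ee = abs(ddg_to_ee(true, tc)[1])
        config = "S" if true > 0 else "R"
        if planted:
            config = "R" if config == "S" else "S"
        records.append(
            ValidationRecord(
                case_id=f"case{i:03d}",
                ligand_id=f"L{(i - 1) % 13 + 1}",
                nucleophile_id=f"N{(i - 1) % 5 + 1}",
                exp_ee=exp_ee,
                exp_config=config,
                pred_ddg=pred,
                temp_K=tc.T,
                exclusion_tag=exclusion_tag if i in excluded else "",
            )
        )
    return records


# ----------------------------------------------------------------------


def _mirror(s: Structure, label: str) -> Structure:
    c = s.coords.copy()
    c[:, 0] *= -1.0
    return s.with_coords(c, label=label)


def make_catalysis_fixture(
    seed: int = 0,
) -> tuple[list[Template], dict[str, Fragment], ForceField]:
    """Mirror-image TS templates + achiral fragments + covering force field.

    The R and S templates are exact mirror images of one chiral core
    carrying three anchor sites (ligand, substrate terminus,
    nucleophile); the fragments are achiral chains. Because the MM
    energy depends only on internal coordinates (and torsions enter
    through cosines), mirror-related assemblies are exactly degenerate —
    the end-to-end chirality null system.
    """
    rng = np.random.default_rng(seed)

    def core(label: str) -> Structure:
        atoms = [
            Atom("Pd", "M"),
            Atom("C", "CA"),
            Atom("N", "NN"),
            Atom(DUMMY_ELEMENT, "DU"),
            Atom(DUMMY_ELEMENT, "DU"),
            Atom(DUMMY_ELEMENT, "DU"),
        ]
        coords = np.array(
            [
                [0.0, 0.0, 0.0],  # M
                [2.1, 0.3, 0.2],  # CA
                [3.2, 1.4, 1.0],  # NN (forming partner)
                [-1.3, 1.2, -0.6],  # Du -> ligand site on M
                [2.6, -1.0, 0.9],  # Du -> substrate site on CA
                [4.5, 1.2, 1.6],  # Du -> nucleophile site on NN
            ]
        )
        bonds = [(0, 1), (1, 2), (0, 3), (1, 4), (2, 5)]
        return Structure(atoms, coords, bonds, forming_bond=(1, 2), label=label)

    sites = [
        AnchorSite("a_ligand", 3, "ligand"),
        AnchorSite("b_substrate", 4, "substrate_terminus"),
        AnchorSite("c_nucleophile", 5, "nucleophile"),
    ]
    t_r = Template(core("exo_R"), sites, product_config="R", allyl_isomer="exo")
    t_s = Template(
        _mirror(core("exo_S"), "exo_S"), sites, product_config="S", allyl_isomer="exo"
    )

    def chain_fragment(types: list[str], cls: str) -> Fragment:
        # dummy first, then a bent chain; attach() re-orients the whole thing
        n = len(types) + 1
        coords = np.zeros((n, 3))
        for i in range(1, n):
            coords[i] = coords[i - 1] + [1.5, 0.35 * ((-1) ** i), 0.1]
        atoms = [Atom(DUMMY_ELEMENT, "DU")] + [Atom("C", t) for t in types]
        bonds = [(i, i + 1) for i in range(n - 1)]
        return Fragment(Structure(atoms, coords, bonds, label=cls), cls)

    # short chains keep the conformational space small enough (two
    # rotatable bonds per assembly) that a brief search fully converges
    # both mirror ensembles — the null probes symmetry, not sampling
    frags = {
        "ligand": chain_fragment(["LG", "LG"], "ligand"),
        "substrate_terminus": chain_fragment(["SB"], "substrate_terminus"),
        "nucleophile": chain_fragment(["NC"], "nucleophile"),
    }

    # discover every typed term the assemblies need, then parameterize
    probe = enumerate_ts(
        [t_r, t_s],
        frags["ligand"],
        frags["substrate_terminus"],
        frags["nucleophile"],
        ff=None,
    )
    stretch_keys: set[tuple] = set()
    bend_keys: set[tuple] = set()
    torsion_keys: set[tuple] = set()
    type_set: set[str] = set()
    for s in probe:
        tp = s.atom_types
        type_set.update(tp)
        ic = build_internals(s, compute_values=False)
        for i, j, _ in ic.bonds:
            k = (tp[i], tp[j])
            if k[::-1] not in stretch_keys:
                stretch_keys.add(k)
        for i, j, k, _ in ic.angles:
            key = (tp[i], tp[j], tp[k])
            if key[::-1] not in bend_keys:
                bend_keys.add(key)
        for i, j, k, l, _ in ic.torsions:
            key = (tp[i], tp[j], tp[k], tp[l])
            if key[::-1] not in torsion_keys:
                torsion_keys.add(key)

    ff = ForceField()
    for key in sorted(stretch_keys):
        forming_like = set(key) == {"CA", "NN"}
        ff.stretch[key] = StretchTerm(
            k=float(rng.uniform(900, 1400))
            if forming_like
            else float(rng.uniform(1800, 2600)),
            r0=float(rng.uniform(1.9, 2.1))
            if forming_like
            else float(rng.uniform(1.45, 1.6)),
        )
    for key in sorted(bend_keys):
        ff.bend[key] = BendTerm(
            k=float(rng.uniform(0.05, 0.1)), theta0=float(rng.uniform(105, 118))
        )
    for key in sorted(torsion_keys):
        ff.torsion[key] = TorsionTerm(
            v1=float(rng.uniform(0, 2)),
            v2=float(rng.uniform(0, 1)),
            v3=float(rng.uniform(3, 7)),
        )
    for t in sorted(type_set):
        ff.vdw[t] = VdwTerm(
            eps=float(rng.uniform(0.2, 0.4)), rstar=float(rng.uniform(3.6, 4.0))
        )
        ff.charge[t] = float(rng.uniform(-0.1, 0.1))
    return [t_r, t_s], frags, ff
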