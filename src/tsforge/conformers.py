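"""Monte-Carlo torsional conformational search with local minimization.

Transition states parameterized as minima can be conformationally
searched like ground states. The search loop: pick a pool member,
perturb a random subset of rotatable torsions by ±(30°–180°), relax to
the nearest local minimum, and collect the result if it lies within an
energy window of the running best. Collection is window-based rather
than Metropolis — every distinct low-energy minimum is kept, matching
conformer-ensemble semantics rather than canonical sampling. All
randomness comes from a single integer-seeded NumPy PCG64 generator, so
ensembles are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .mmcore import (
    CompiledSystem,
    ForceField,
    MinimizationError,
    Structure,
    minimize_compiled,
    superpose_rmsd,
)

__all__ = [
    "SearchOptions",
    "TSEnsemble",
    "rotatable_torsions",
    "mc_search",
    "dedupe",
    "merge_ensembles",
]


@dataclass
class SearchOptions:
    """Knobs of the Monte-Carlo conformer search.

    ``n_steps`` defaults to 40000 for production searches of full TS
    models; tests and fixtures use far fewer. ``window`` is the energy
    window above the best minimum within which conformers are retained
    (kJ·mol⁻¹); ``rmsd_tol``/``energy_tol`` define duplicates.
    """

    n_steps: int = 40000
    seed: int | None = 0
    max_perturbed: int = 3
    min_rotation: float = 30.0  # deg
    max_rotation: float = 180.0  # deg
    window: float = 21.0  # kJ·mol⁻¹
    rmsd_tol: float = 0.25  # Å
    energy_tol: float = 0.1  # kJ·mol⁻¹
    grad_tol: float = 1e-3  # kJ·mol⁻¹·Å⁻¹, minimizer target
    max_min_steps: int = 500

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.window <= 0:
            raise ValueError("energy window must be positive")


@dataclass
class TSEnsemble:
    """Conformers of one diastereomeric pathway, sorted by energy.

    ``label`` carries the product configuration of the parent TS
    (e.g. "exo_S"); ``conformers`` is a list of (energy, coords).
    """

    label: str
    conformers: list[tuple[float, np.ndarray]] = field(default_factory=list)

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for e, _ in self.conformers], dtype=float)


def rotatable_torsions(s: Structure) -> list[tuple[int, int, int, int]]:
    """One torsion quadruple per rotatable bond, deterministic order.

    A bond is rotatable when it is acyclic, both atoms have at least one
    further neighbor, and it is not the forming bond (the TS reaction
    coordinate is never driven). The representative quadruple uses the
    lowest-index outer neighbors.
    """
    g = s.graph()
    ring_edges: set[tuple[int, int]] = set()
    for cycle in nx.cycle_basis(g):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            ring_edges.add((min(a, b), max(a, b)))
    out = []
    for i, j in sorted(s.bonds):
        if (i, j) in ring_edges or (i, j) == s.forming_bond:
            continue
        ni = sorted(n for n in g.neighbors(i) if n != j)
        nj = sorted(n for n in g.neighbors(j) if n != i)
        if not ni or not nj:
            continue
        out.append((ni[0], i, j, nj[0]))
    return out


def _rotation_partition(s: Structure) -> dict[tuple[int, int], np.ndarray]:
    """For each rotatable bond (i, j): indices of atoms moved with j."""
    g = s.graph()
    parts = {}
    for quad in rotatable_torsions(s):
        _, i, j, _ = quad
        g.remove_edge(i, j)
        moved = sorted(nx.node_connected_component(g, j))
        g.add_edge(i, j)
        parts[(i, j)] = np.array(moved, dtype=int)
    return parts


def _rotate_about_bond(
    coords: np.ndarray, i: int, j: int, moved: np.ndarray, angle_deg: float
) -> None:
    """Rotate ``moved`` atoms about the i→j axis, in place."""
    axis = coords[j] - coords[i]
    n = np.linalg.norm(axis)
    if n < 1e-10:
        return
    axis = axis / n
    t = np.radians(angle_deg)
    c, s_ = np.cos(t), np.sin(t)
    k = axis
    rel = coords[moved] - coords[j]
    coords[moved] = (
        rel * c
        + np.cross(k, rel) * s_
        + np.outer(rel @ k, k) * (1 - c)
        + coords[j]
    )


def dedupe(
    pool: list[tuple[float, np.ndarray]],
    rmsd_tol: float = 0.25,
    energy_tol: float = 0.1,
    label: str = "",
) -> TSEnsemble:
    """Cluster a conformer pool, keeping each cluster's lowest-energy member.

    Two conformers are duplicates when both their superposition RMSD is
    below ``rmsd_tol`` and their energies differ by less than
    ``energy_tol``. Greedy pass in ascending energy order.
    """
    if not pool:
        raise ValueError("empty conformer pool")
    ordered = sorted(pool, key=lambda t: t[0])
    kept: list[tuple[float, np.ndarray]] = []
    for e, c in ordered:
        dup = any(
            abs(e - e2) < energy_tol and superpose_rmsd(c, c2) < rmsd_tol
            for e2, c2 in kept
        )
        if not dup:
            kept.append((e, np.array(c)))
    return TSEnsemble(label=label, conformers=kept)


def mc_search(s: Structure, ff: ForceField, opts: SearchOptions) -> TSEnsemble:
    """Seeded Monte-Carlo torsional search of ``s`` under ``ff``.

    Returns the deduplicated ensemble of minima within ``opts.window``
    of the best energy found, sorted ascending. Reproducible bit-wise
    for a fixed seed. Aborts if more than half the minimization attempts
    fail.
    """
    system = CompiledSystem(s, ff)
    rng = np.random.default_rng(opts.seed)
    x0, e0, _, _, _ = minimize_compiled(
        system, s.coords, opts.max_min_steps, opts.grad_tol
    )
    torsions = rotatable_torsions(s)
    parts = _rotation_partition(s)
    pool: list[tuple[float, np.ndarray]] = [(e0, x0)]
    if not torsions:
        return TSEnsemble(label=s.label, conformers=pool)

    best = e0
    n_fail = 0
    for step in range(opts.n_steps):
        base = pool[int(rng.integers(len(pool)))][1]
        n_pert = int(rng.integers(1, min(opts.max_perturbed, len(torsions)) + 1))
        chosen = rng.choice(len(torsions), size=n_pert, replace=False)
        cand = np.array(base)
        for idx in np.sort(chosen):
            _, i, j, _ = torsions[idx]
            mag = rng.uniform(opts.min_rotation, opts.max_rotation)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            _rotate_about_bond(cand, i, j, parts[(i, j)], sign * mag)
        try:
            xm, em, _, _, _ = minimize_compiled(
                system, cand, opts.max_min_steps, opts.grad_tol
            )
        except MinimizationError:
            n_fail += 1
            if n_fail > max(10, opts.n_steps // 2):
                raise MinimizationError(
                    f"more than half of {step + 1} MC steps failed to minimize"
                )
            continue
        if em < best + opts.window:
            best = min(best, em)
            dup = False
            for idx, (e2, c2) in enumerate(pool):
                if abs(em - e2) < opts.energy_tol and superpose_rmsd(xm, c2) < opts.rmsd_tol:
                    if em < e2:
                        pool[idx] = (em, xm)
                    dup = True
                    break
            if not dup:
                pool.append((em, xm))
            pool = [(e, c) for e, c in pool if e <= best + opts.window]

    ens = dedupe(pool, opts.rmsd_tol, opts.energy_tol, label=s.label)
    ens.conformers = [
        (e, c) for e, c in ens.conformers if e <= ens.conformers[0][0] + opts.window
    ]
    return ens


def merge_ensembles(ensembles: list[TSEnsemble], label: str, window: float | None = None) -> TSEnsemble:
    """Pool ensembles of one pathway (possibly different parent structures).

    Conformers from different parents are not RMSD-deduplicated against
    each other (atom orderings may differ); the pooled list is sorted
    and optionally re-filtered to ``window`` above the pooled minimum.
    """
    conformers = sorted(
        (c for ens in ensembles for c in ens.conformers), key=lambda t: t[0]
    )
    if window is not None and conformers:
        emin = conformers[0][0]
        conformers = [(e, c) for e, c in conformers if e <= emin + window]
    return TSEnsemble(label=label, conformers=conformers)
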