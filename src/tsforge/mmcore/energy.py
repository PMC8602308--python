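"""MM3-like potential energy, analytic gradient and numerical Hessian.

Functional form (units: Å, degrees, kJ·mol⁻¹, elementary charge):

* stretch   E = ½ k_b (r − r0)²
* bend      E = ½ k_a (θ − θ0)²                 (θ in degrees)
* torsion   E = ½ [V1(1+cosφ) + V2(1−cos2φ) + V3(1+cos3φ)]
* vdW       E = ε [1.84×10⁵ e^(−12 r/r*) − 2.25 (r*/r)⁶]
* Coulomb   E = 1389.35 q_i q_j / (ε_d r)

Nonbonded terms run over atom pairs separated by three or more bonds
(1-2 and 1-3 excluded, 1-4 counted in full) and over pairs in different
connected components. Below the radius where the exp-6 slope changes
sign (r < 0.302035 r*) the potential is continued by a quadratic
repulsive wall so minimization cannot fall through to E → −∞.

The analytic gradient is exact for this form; the Hessian is obtained
by central finite differences of the analytic gradient and symmetrized.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .forcefield import COULOMB_K, ForceField
from .internals import build_internals
from .structure import Structure

__all__ = ["CompiledSystem", "energy", "gradient", "energy_and_gradient", "hessian"]

_EXP6_A = 1.84e5
_EXP6_B = 12.0
_EXP6_C = 2.25
#: r/r* at which the exp-6 slope changes sign (start of the quadratic wall).
_EXP6_XC = 0.3020348764369603
#: wall energy at the turnover, in units of ε.
_EXP6_EWALL = _EXP6_A * np.exp(-_EXP6_B * _EXP6_XC) - _EXP6_C * _EXP6_XC ** -6
_RAD = np.pi / 180.0


class CompiledSystem:
    """Structure topology + force field flattened into index/parameter arrays.

    Building the system resolves every typed term once; a missing record
    raises :class:`~tsforge.mmcore.forcefield.MissingParameterError`
    naming the offending type tuple. Energy evaluations then take bare
    coordinate arrays, which keeps minimization and Hessian loops cheap.
    """

    def __init__(self, s: Structure, ff: ForceField):
        self.n_atoms = s.n_atoms
        tp = s.atom_types
        ic = build_internals(s, compute_values=False)

        self.b_idx = np.array([(i, j) for i, j, _ in ic.bonds], dtype=int).reshape(-1, 2)
        terms = [ff.stretch_for(tp[i], tp[j]) for i, j, _ in ic.bonds]
        self.b_k = np.array([t.k for t in terms])
        self.b_r0 = np.array([t.r0 for t in terms])

        self.a_idx = np.array(
            [(i, j, k) for i, j, k, _ in ic.angles], dtype=int
        ).reshape(-1, 3)
        terms = [ff.bend_for(tp[i], tp[j], tp[k]) for i, j, k, _ in ic.angles]
        self.a_k = np.array([t.k for t in terms])
        self.a_t0 = np.array([t.theta0 for t in terms])

        self.t_idx = np.array(
            [(i, j, k, l) for i, j, k, l, _ in ic.torsions], dtype=int
        ).reshape(-1, 4)
        terms = [ff.torsion_for(tp[i], tp[j], tp[k], tp[l]) for i, j, k, l, _ in ic.torsions]
        self.t_v1 = np.array([t.v1 for t in terms])
        self.t_v2 = np.array([t.v2 for t in terms])
        self.t_v3 = np.array([t.v3 for t in terms])

        # nonbonded pair list: graph separation >= 3 bonds (or disconnected)
        g = s.graph()
        excluded: set[tuple[int, int]] = set()
        for i, lengths in nx.all_pairs_shortest_path_length(g, cutoff=2):
            for j, d in lengths.items():
                if i < j and d >= 1:
                    excluded.add((i, j))
        pairs = [
            (i, j)
            for i in range(self.n_atoms)
            for j in range(i + 1, self.n_atoms)
            if (i, j) not in excluded
        ]
        self.nb_idx = np.array(pairs, dtype=int).reshape(-1, 2)
        eps = np.empty(len(pairs))
        rstar = np.empty(len(pairs))
        qq = np.empty(len(pairs))
        q = ff.effective_charges(s)
        for a in s.atoms:
            ff.vdw_for(a.atom_type)  # coverage check even for excluded atoms
        for m, (i, j) in enumerate(pairs):
            vi, vj = ff.vdw_for(tp[i]), ff.vdw_for(tp[j])
            # Lorentz-Berthelot-style combination
            eps[m] = np.sqrt(vi.eps * vj.eps)
            rstar[m] = 0.5 * (vi.rstar + vj.rstar)
            qq[m] = COULOMB_K * q[i] * q[j] / ff.dielectric
        self.nb_eps = eps
        self.nb_rstar = rstar
        self.nb_qq = qq

    # ------------------------------------------------------------------

    def energy_and_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        e = 0.0
        g = np.zeros_like(x)

        if len(self.b_idx):
            i, j = self.b_idx[:, 0], self.b_idx[:, 1]
            d = x[i] - x[j]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.b_r0
            e += 0.5 * np.sum(self.b_k * dr * dr)
            f = (self.b_k * dr / r)[:, None] * d
            np.add.at(g, i, f)
            np.add.at(g, j, -f)

        if len(self.a_idx):
            ai, aj, ak = self.a_idx[:, 0], self.a_idx[:, 1], self.a_idx[:, 2]
            u = x[ai] - x[aj]
            v = x[ak] - x[aj]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
            s = np.sqrt(np.maximum(1.0 - c * c, 1e-16))
            theta = np.degrees(np.arccos(c))
            dth = theta - self.a_t0
            e += 0.5 * np.sum(self.a_k * dth * dth)
            # dE/dθ_rad = k (θ_deg − θ0_deg) · (180/π)
            pref = self.a_k * dth / _RAD
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            dthi = (c[:, None] * uh - vh) / (nu * s)[:, None]
            dthk = (c[:, None] * vh - uh) / (nv * s)[:, None]
            np.add.at(g, ai, pref[:, None] * dthi)
            np.add.at(g, ak, pref[:, None] * dthk)
            np.add.at(g, aj, -pref[:, None] * (dthi + dthk))

        if len(self.t_idx):
            ti, tj, tk, tl = (self.t_idx[:, m] for m in range(4))
            b1 = x[tj] - x[ti]
            b2 = x[tk] - x[tj]
            b3 = x[tl] - x[tk]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-16)
            n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-16)
            phi = np.arctan2(
                np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.maximum(nb2, 1e-16),
                np.einsum("ij,ij->i", n1, n2),
            )
            e += 0.5 * np.sum(
                self.t_v1 * (1 + np.cos(phi))
                + self.t_v2 * (1 - np.cos(2 * phi))
                + self.t_v3 * (1 + np.cos(3 * phi))
            )
            dedphi = 0.5 * (
                -self.t_v1 * np.sin(phi)
                + 2 * self.t_v2 * np.sin(2 * phi)
                - 3 * self.t_v3 * np.sin(3 * phi)
            )
            # Blondel–Karplus torsion derivatives
            dphi_i = -(nb2 / n1sq)[:, None] * n1
            dphi_l = (nb2 / n2sq)[:, None] * n2
            s12 = np.einsum("ij,ij->i", b1, b2) / np.maximum(nb2 * nb2, 1e-16)
            s32 = np.einsum("ij,ij->i", b3, b2) / np.maximum(nb2 * nb2, 1e-16)
            dphi_j = -(1.0 + s12)[:, None] * dphi_i + s32[:, None] * dphi_l
            dphi_k = s12[:, None] * dphi_i - (1.0 + s32)[:, None] * dphi_l
            np.add.at(g, ti, dedphi[:, None] * dphi_i)
            np.add.at(g, tj, dedphi[:, None] * dphi_j)
            np.add.at(g, tk, dedphi[:, None] * dphi_k)
            np.add.at(g, tl, dedphi[:, None] * dphi_l)

        if len(self.nb_idx):
            i, j = self.nb_idx[:, 0], self.nb_idx[:, 1]
            d = x[i] - x[j]
            r = np.linalg.norm(d, axis=1)
            rc = _EXP6_XC * self.nb_rstar
            inner = r < rc
            ex = np.exp(-_EXP6_B * r / self.nb_rstar)
            x6 = (self.nb_rstar / np.maximum(r, 1e-16)) ** 6
            ev = self.nb_eps * (_EXP6_A * ex - _EXP6_C * x6)
            dev = self.nb_eps * (
                -_EXP6_B / self.nb_rstar * _EXP6_A * ex
                + 6 * _EXP6_C * x6 / np.maximum(r, 1e-16)
            )
            if np.any(inner):
                kwall = 1.0e5 * self.nb_eps / self.nb_rstar ** 2
                dr = r - rc
                ev = np.where(inner, self.nb_eps * _EXP6_EWALL + 0.5 * kwall * dr * dr, ev)
                dev = np.where(inner, kwall * dr, dev)
            ec = self.nb_qq / np.maximum(r, 1e-16)
            dec = -self.nb_qq / np.maximum(r * r, 1e-16)
            e += float(np.sum(ev + ec))
            f = ((dev + dec) / np.maximum(r, 1e-16))[:, None] * d
            np.add.at(g, i, f)
            np.add.at(g, j, -f)

        return float(e), g

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_and_gradient(coords)[0]

    def hessian(self, coords: np.ndarray, step: float = 1e-4) -> np.ndarray:
        """Central finite differences of the analytic gradient, symmetrized."""
        x = np.asarray(coords, dtype=float).reshape(-1).copy()
        n = x.size
        h = np.empty((n, n))
        for m in range(n):
            x[m] += step
            _, gp = self.energy_and_gradient(x.reshape(-1, 3))
            x[m] -= 2 * step
            _, gm = self.energy_and_gradient(x.reshape(-1, 3))
            x[m] += step
            h[m] = (gp - gm).reshape(-1) / (2 * step)
        return 0.5 * (h + h.T)


# -- structure-level convenience wrappers ------------------------------


def energy(s: Structure, ff: ForceField) -> float:
    """Total MM energy of ``s`` under ``ff`` in kJ·mol⁻¹."""
    return CompiledSystem(s, ff).energy(s.coords)


def energy_and_gradient(s: Structure, ff: ForceField) -> tuple[float, np.ndarray]:
    return CompiledSystem(s, ff).energy_and_gradient(s.coords)


def gradient(s: Structure, ff: ForceField) -> np.ndarray:
    """Analytic ∂E/∂x, shape (N, 3), kJ·mol⁻¹·Å⁻¹."""
    return CompiledSystem(s, ff).energy_and_gradient(s.coords)[1]


def hessian(s: Structure, ff: ForceField, step: float = 1e-4) -> np.ndarray:
    """Symmetrized 3N×3N Hessian in kJ·mol⁻¹·Å⁻²."""
    return CompiledSystem(s, ff).hessian(s.coords, step=step)
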