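"""Unit tests for the molecular-mechanics core."""

import numpy as np
import pytest

from tsforge.mmcore import (
    Atom,
    BendTerm,
    CompiledSystem,
    ForceField,
    MissingParameterError,
    StretchTerm,
    Structure,
    StructureError,
    TorsionTerm,
    VdwTerm,
    bond_angle,
    bond_length,
    build_internals,
    dihedral,
    energy,
    minimize,
    superpose_rmsd,
    wrap_angle,
)
from tsforge.synthfix import ToySpec, make_toy_ts_system

from conftest import finite_difference_gradient


def two_atom_ff():
    ff = ForceField()
    ff.stretch[("A", "A")] = StretchTerm(k=2000.0, r0=1.5)
    ff.vdw["A"] = VdwTerm(eps=0.3, rstar=3.8)
    ff.charge["A"] = 0.0
    return ff


def test_structure_validates_forming_bond_membership():
    atoms = [Atom("C", "A"), Atom("C", "A"), Atom("C", "A")]
    coords = np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]], dtype=float)
    with pytest.raises(StructureError):
        Structure(atoms, coords, [(0, 1), (1, 2)], forming_bond=(0, 2))


def test_bond_normalization_and_graph():
    atoms = [Atom("C", "A"), Atom("C", "A")]
    s = Structure(atoms, np.array([[0.0, 0, 0], [1.5, 0, 0]]), [(1, 0)])
    assert s.bonds == [(0, 1)]
    assert set(s.graph().edges) == {(0, 1)}


def test_internal_coordinate_values():
    # right-angle planar chain: bond 1.0, angle 90, trans dihedral 180
    atoms = [Atom("C", "A") for _ in range(4)]
    coords = np.array(
        [[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, -1.0, 0.0]]
    )
    s = Structure(atoms, coords, [(0, 1), (1, 2), (2, 3)])
    assert bond_length(coords, 0, 1) == pytest.approx(1.0)
    assert bond_angle(coords, 0, 1, 2) == pytest.approx(90.0)
    assert abs(dihedral(coords, 0, 1, 2, 3)) == pytest.approx(180.0)
    # cis arrangement gives 0
    coords_cis = coords.copy()
    coords_cis[3] = [1.0, 1.0, 0.0]
    assert dihedral(coords_cis, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-10)
    ic = build_internals(s)
    assert len(ic.bonds) == 3 and len(ic.angles) == 2 and len(ic.torsions) == 1


def test_wrap_angle_range():
    for a in (-720.0, -180.0, -179.9, 0.0, 179.9, 180.0, 540.0):
        w = wrap_angle(a)
        assert -180.0 < w <= 180.0
        assert np.cos(np.radians(w)) == pytest.approx(np.cos(np.radians(a)))


def test_stretch_energy_quadratic():
    ff = two_atom_ff()
    atoms = [Atom("C", "A"), Atom("C", "A")]
    for dr in (0.1, -0.05, 0.2):
        s = Structure(
            atoms, np.array([[0.0, 0, 0], [1.5 + dr, 0, 0]]), [(0, 1)]
        )
        assert energy(s, ff) == pytest.approx(0.5 * 2000.0 * dr**2)


def test_missing_parameter_raises():
    ff = two_atom_ff()
    atoms = [Atom("C", "A"), Atom("C", "B")]
    s = Structure(atoms, np.array([[0.0, 0, 0], [1.5, 0, 0]]), [(0, 1)])
    with pytest.raises(MissingParameterError):
        CompiledSystem(s, ff)


def test_nonbonded_excludes_below_three_bonds(toy_system):
    """1-2 and 1-3 pairs carry no vdW/Coulomb term: moving only those
    distances at fixed bonded internals leaves the nonbonded sum over
    excluded pairs absent from the compiled pair list."""
    s, ff = toy_system
    cs = CompiledSystem(s, ff)
    g = s.graph()
    import networkx as nx

    dist = dict(nx.all_pairs_shortest_path_length(g))
    for i, j in map(tuple, cs.nb_idx):
        assert dist[i][j] >= 3


def test_gradient_matches_fd_on_toy(toy_system):
    s, ff = toy_system
    cs = CompiledSystem(s, ff)
    rng = np.random.default_rng(1)
    coords = s.coords + rng.normal(0, 0.05, s.coords.shape)
    _, g = cs.energy_and_gradient(coords)
    gfd = finite_difference_gradient(cs, coords)
    assert np.abs(g - gfd).max() < 1e-5 * max(1.0, np.abs(gfd).max())


def test_energy_rigid_motion_invariance(toy_system):
    s, ff = toy_system
    cs = CompiledSystem(s, ff)
    e0 = cs.energy_and_gradient(s.coords)[0]
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("xyz", [30, -40, 75], degrees=True).as_matrix()
    moved = s.coords @ rot.T + np.array([5.0, -3.0, 2.0])
    e1 = cs.energy_and_gradient(moved)[0]
    assert abs(e1 - e0) < 1e-8


def test_hessian_symmetric_and_rotation_modes(toy_system):
    s, ff = toy_system
    h = CompiledSystem(s, ff).hessian(s.coords)
    assert np.allclose(h, h.T)
    w = np.linalg.eigvalsh(h)
    # minimized structure: six rigid modes near zero, the rest positive
    assert np.abs(w[:6]).max() < 1.0
    assert w[6] > 1.0


def test_minimize_reaches_tolerance():
    s, ff = make_toy_ts_system(ToySpec(n_rotatable=2, seed=3))
    rng = np.random.default_rng(0)
    perturbed = s.with_coords(s.coords + rng.normal(0, 0.05, s.coords.shape))
    res = minimize(perturbed, ff, grad_tol=0.01)
    assert res.converged
    assert res.grad_rms <= 0.01
    assert res.energy <= energy(perturbed, ff)


def test_superpose_rmsd_zero_for_rotated_copy(toy_system):
    s, _ = toy_system
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("zyx", [12, 120, -77], degrees=True).as_matrix()
    moved = s.coords @ rot.T + 4.2
    assert superpose_rmsd(s.coords, moved) < 1e-10


def test_superpose_rmsd_detects_real_difference(toy_system):
    s, _ = toy_system
    other = s.coords.copy()
    other[0] += [1.0, 0, 0]
    assert superpose_rmsd(s.coords, other) > 0.1
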