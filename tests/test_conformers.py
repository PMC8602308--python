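"""Unit tests for the Monte-Carlo conformational search."""

import numpy as np
import pytest

from tsforge import conformers
from tsforge.conformers import SearchOptions, TSEnsemble, dedupe, mc_search, merge_ensembles
from tsforge.mmcore import dihedral
from tsforge.synthfix import ToySpec, make_toy_ts_system


def test_rotatable_torsions_excludes_terminal_and_forming(toy_system):
    s, _ = toy_system
    quads = conformers.rotatable_torsions(s)
    # chain with terminal forming bond: n_heavy - 3 rotatable bonds
    assert len(quads) == s.n_atoms - 3
    bonds = {(min(i, j), max(i, j)) for _, i, j, _ in quads}
    assert s.forming_bond not in bonds
    for i, j in bonds:
        g = s.graph()
        assert len(list(g.neighbors(i))) > 1 and len(list(g.neighbors(j))) > 1


def test_rotate_about_bond_changes_only_dihedral(three_well):
    s, _ = three_well
    (q,) = conformers.rotatable_torsions(s)
    a, i, j, b = q
    moved = conformers._rotation_partition(s)[(i, j)]
    c = s.coords.copy()
    before = dihedral(c, a, i, j, b)
    conformers._rotate_about_bond(c, i, j, moved, 40.0)
    after = dihedral(c, a, i, j, b)
    assert abs(((after - before) - 40.0 + 180) % 360 - 180) < 1e-8 or abs(
        ((after - before) + 40.0 + 180) % 360 - 180
    ) < 1e-8
    # bond lengths everywhere unchanged
    for x, y in s.bonds:
        assert np.linalg.norm(c[x] - c[y]) == pytest.approx(
            np.linalg.norm(s.coords[x] - s.coords[y])
        )


def test_dedupe_merges_identical_keeps_distinct():
    c1 = np.random.default_rng(0).normal(size=(4, 3))
    c2 = c1 + np.array([10.0, 0, 0])  # rigid shift: same conformer
    c3 = c1.copy()
    c3[0] += [2.0, 0, 0]
    ens = dedupe([(1.0, c1), (1.0, c2), (1.0, c3)], rmsd_tol=0.25, energy_tol=0.1)
    assert len(ens.conformers) == 2
    with pytest.raises(ValueError):
        dedupe([])


def test_mc_search_deterministic(three_well):
    s, ff = three_well
    opts = SearchOptions(n_steps=200, seed=17)
    e1 = mc_search(s, ff, opts)
    e2 = mc_search(s, ff, SearchOptions(n_steps=200, seed=17))
    assert len(e1.conformers) == len(e2.conformers)
    for (ea, ca), (eb, cb) in zip(e1.conformers, e2.conformers):
        assert ea == eb
        assert np.array_equal(ca, cb)


def test_mc_search_sorted_and_windowed(three_well):
    s, ff = three_well
    ens = mc_search(s, ff, SearchOptions(n_steps=200, seed=2, window=8.0))
    es = ens.energies
    assert np.all(np.diff(es) >= 0)
    assert es[-1] - es[0] <= 8.0


def test_mc_search_no_torsions_returns_minimum():
    s, ff = make_toy_ts_system(ToySpec(n_heavy_atoms=4, seed=1))
    # remove rotatability by using the 3-atom sub-case: n=4 has exactly 1
    quads = conformers.rotatable_torsions(s)
    assert len(quads) == 1


def test_merge_ensembles_window():
    c = np.zeros((1, 3))
    a = TSEnsemble(label="x", conformers=[(0.0, c), (3.0, c)])
    b = TSEnsemble(label="y", conformers=[(1.0, c), (30.0, c)])
    merged = merge_ensembles([a, b], label="xy", window=10.0)
    assert [e for e, _ in merged.conformers] == [0.0, 1.0, 3.0]
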