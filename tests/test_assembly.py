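"""Unit tests for TS assembly from templates and fragments."""

import numpy as np
import pytest

from tsforge import assembly
from tsforge.assembly import attach, canonical_order, enumerate_ts
from tsforge.mmcore import superpose_rmsd


def test_enumerate_produces_labeled_pair(catalysis):
    templates, frags, ff = catalysis
    structures = enumerate_ts(
        templates,
        frags["ligand"],
        frags["substrate_terminus"],
        frags["nucleophile"],
        ff=ff,
    )
    labels = sorted(s.label for s in structures)
    assert labels == ["exo_R", "exo_S"]
    for s in structures:
        assert s.forming_bond is not None
        assert all(a.element != "Du" for a in s.atoms)  # no dummies survive


def test_attach_places_fragment_at_equilibrium_distance(catalysis):
    templates, frags, ff = catalysis
    t = templates[0]
    before = t.structure.n_atoms
    frag = frags["ligand"]
    s = attach(t, frag, "a_ligand", ff=ff)
    # dummy removed from host and fragment, real atoms concatenated
    assert s.n_atoms == before - 2 + frag.structure.n_atoms
    # new bond exists between the two anchor neighbours at the FF r0
    host_anchor = 0  # site a_ligand hangs off the metal (atom 0)
    new_atom = before - 1  # first fragment atom after dummy removal
    assert (
        min(host_anchor, new_atom),
        max(host_anchor, new_atom),
    ) in s.bonds
    ti = s.atoms[host_anchor].atom_type
    tj = s.atoms[new_atom].atom_type
    r0 = ff.stretch_for(ti, tj).r0
    d = np.linalg.norm(s.coords[host_anchor] - s.coords[new_atom])
    assert d == pytest.approx(r0, abs=1e-6)


def test_attach_rejects_wrong_class(catalysis):
    templates, frags, _ = catalysis
    with pytest.raises(ValueError):
        attach(templates[0], frags["ligand"], "b_substrate")


def test_mirror_templates_are_enantiomeric(catalysis):
    """Mirror assemblies superpose only after reflection."""
    templates, frags, ff = catalysis
    r, s_ = enumerate_ts(
        templates,
        frags["ligand"],
        frags["substrate_terminus"],
        frags["nucleophile"],
        ff=ff,
    )
    direct = superpose_rmsd(r.coords, s_.coords)
    reflected = superpose_rmsd(r.coords, s_.coords * np.array([-1.0, 1.0, 1.0]))
    # mirror equivalence holds to the 1° resolution of the attachment
    # torsion scan (floating-point ties can shift one grid point)
    assert reflected < 0.05
    assert direct > 0.1


def test_enumerate_order_independent(catalysis):
    """Assembled geometry must not depend on template list order."""
    templates, frags, ff = catalysis
    fwd = enumerate_ts(
        templates,
        frags["ligand"],
        frags["substrate_terminus"],
        frags["nucleophile"],
        ff=ff,
    )
    rev = enumerate_ts(
        templates[::-1],
        frags["ligand"],
        frags["substrate_terminus"],
        frags["nucleophile"],
        ff=ff,
    )
    by_label_fwd = {s.label: s for s in fwd}
    by_label_rev = {s.label: s for s in rev}
    assert by_label_fwd.keys() == by_label_rev.keys()
    for label in by_label_fwd:
        a, b = by_label_fwd[label], by_label_rev[label]
        ca = canonical_order(a)
        cb = canonical_order(b)
        assert np.allclose(ca.coords, cb.coords)
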