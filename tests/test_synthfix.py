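"""Unit tests for the synthetic fixture generators."""

import numpy as np
import pytest

from tsforge import proofread, q2mm
from tsforge.mmcore import CompiledSystem
from tsforge.synthfix import (
    ToySpec,
    make_three_well_system,
    make_toy_ts_system,
    make_validation_fixture,
    mock_qm_reference,
    perturb_ff,
)


def test_toyspec_counting_example():
    s, _ = make_toy_ts_system(ToySpec(n_heavy_atoms=4, seed=0))
    assert s.n_atoms == 4
    from tsforge.conformers import rotatable_torsions

    assert len(rotatable_torsions(s)) == 1
    with pytest.raises(ValueError):
        ToySpec(n_heavy_atoms=4, n_rotatable=3)  # inconsistent
    with pytest.raises(ValueError):
        ToySpec(n_heavy_atoms=25)  # beyond desk scale


def test_toy_system_reproducible_bitwise():
    a, ffa = make_toy_ts_system(ToySpec(n_rotatable=2, seed=9))
    b, ffb = make_toy_ts_system(ToySpec(n_rotatable=2, seed=9))
    assert np.array_equal(a.coords, b.coords)
    assert [f.atom_type for f in a.atoms] == [f.atom_type for f in b.atoms]
    for key in ffa.param_keys():
        assert ffa.get_param(key) == ffb.get_param(key)
    c, _ = make_toy_ts_system(ToySpec(n_rotatable=2, seed=10))
    assert not np.array_equal(a.coords, c.coords)


def test_toy_system_is_minimized():
    s, ff = make_toy_ts_system(ToySpec(n_rotatable=3, seed=4))
    _, g = CompiledSystem(s, ff).energy_and_gradient(s.coords)
    assert np.sqrt((g**2).mean()) < 0.01


def test_mock_reference_self_consistency(toy_system, toy_reference):
    _, ff_true = toy_system
    assert q2mm.penalty(ff_true, [toy_reference], q2mm.PenaltyConfig()) < 1e-6


def test_mock_reference_requires_forming_bond():
    s, ff = make_toy_ts_system(ToySpec(n_heavy_atoms=5, include_forming_bond=False, seed=2))
    with pytest.raises(ValueError):
        mock_qm_reference(s, ff, ts=True)


def test_mock_reference_charge_noise_statistics():
    """Charge residual RMS ≈ w_charge · noise_sd · √N over many seeds."""
    s, ff = make_toy_ts_system(ToySpec(n_rotatable=1, seed=6))
    cfg = q2mm.PenaltyConfig()
    noise_sd = 0.01
    sq = []
    for seed in range(100):
        ref = mock_qm_reference(s, ff, noise_sd=noise_sd, seed=seed)
        sq.append(q2mm.penalty(ff, [ref], cfg))
    # all non-charge residuals vanish, so penalty = w² Σ noise²
    expected = (cfg.weights["charge"] * noise_sd) ** 2 * s.n_atoms
    assert np.mean(sq) == pytest.approx(expected, rel=0.3)


def test_perturb_ff_limits_and_seeding(toy_system):
    _, ff = toy_system
    tiny = perturb_ff(ff, 1e-12, seed=0)
    for key in ff.param_keys():
        assert tiny.get_param(key) == pytest.approx(ff.get_param(key), rel=1e-9)
    p1 = perturb_ff(ff, 0.2, seed=1)
    p2 = perturb_ff(ff, 0.2, seed=2)
    assert any(p1.get_param(k) != p2.get_param(k) for k in ff.param_keys())
    for key in ff.param_keys():
        ratio = p1.get_param(key) / ff.get_param(key) if ff.get_param(key) else 1.0
        if ff.get_param(key):
            assert 0.8 - 1e-9 <= abs(ratio) <= 1.2 + 1e-9


def test_three_well_fixture_shape(three_well):
    s, ff = three_well
    from tsforge.conformers import rotatable_torsions

    assert s.n_atoms == 4
    assert len(rotatable_torsions(s)) == 1
    _, g = CompiledSystem(s, ff).energy_and_gradient(s.coords)
    assert np.sqrt((g**2).mean()) < 1e-4


def test_validation_fixture_planted_design(validation_records):
    records = validation_records
    assert len(records) == 77
    tagged = [r for r in records if r.exclusion_tag == "indphox"]
    assert len(tagged) == 5
    kept = [r for r in records if not r.exclusion_tag]
    flagged = proofread.flag_mismatches(kept)
    planted = {records[i - 1].case_id for i in range(1, 12)}
    assert set(flagged) == planted


def test_validation_fixture_no_errors_perfect():
    records = make_validation_fixture(n=20, error_sd_kJmol=0.0, mismatch_ids=[], seed=3)
    rep = proofread.report(records)
    assert rep.initial.mue == pytest.approx(0.0, abs=1e-9)
    assert rep.initial.r2 == pytest.approx(1.0)
    assert rep.n_flagged == 0


def test_validation_fixture_mue_matches_half_normal():
    """Mean MUE over many seeds ≈ sd·√(2/π) for clean (unplanted) tables."""
    sd = 2.0
    mues = [
        proofread.mue(make_validation_fixture(n=77, error_sd_kJmol=sd, mismatch_ids=[], seed=s))
        for s in range(200)
    ]
    assert np.mean(mues) == pytest.approx(sd * np.sqrt(2 / np.pi), rel=0.05)


def test_catalysis_fixture_covering_ff(catalysis):
    templates, frags, ff = catalysis
    from tsforge.assembly import enumerate_ts

    structures = enumerate_ts(
        templates, frags["ligand"], frags["substrate_terminus"], frags["nucleophile"], ff=ff
    )
    for s in structures:
        ff.validate_coverage(s)  # raises on any missing term
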