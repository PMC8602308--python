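"""Unit tests for the Q2MM fitting machinery."""

import numpy as np
import pytest

from tsforge import q2mm
from tsforge.mmcore import hessian as mm_hessian
from tsforge.q2mm import (
    NotFirstOrderSaddleError,
    PenaltyConfig,
    ReferenceStructure,
    fit,
    internal_validate,
    modify_ts_hessian,
    penalty,
)
from tsforge.synthfix import ToySpec, make_toy_ts_system, mock_qm_reference, perturb_ff


def forming_keys(s):
    i, j = s.forming_bond
    ti, tj = s.atoms[i].atom_type, s.atoms[j].atom_type
    return [f"stretch/{ti},{tj}/k", f"stretch/{ti},{tj}/r0"]


def test_reference_requires_symmetric_hessian(toy_system):
    s, ff = toy_system
    h = mm_hessian(s, ff)
    bad = h.copy()
    bad[0, 1] += 1.0
    with pytest.raises(ValueError):
        ReferenceStructure(
            structure=s,
            hessian_ref=bad,
            charges_ref=np.array(s.charges),
            internals_ref=None,
        )


def test_mock_reference_is_first_order_saddle(toy_reference):
    w = np.linalg.eigvalsh(toy_reference.hessian_ref)
    assert (w < -q2mm.EPS_NEG).sum() == 1


def test_modify_ts_hessian_replaces_only_negative_mode(toy_reference):
    h = toy_reference.hessian_ref
    omega = 1234.5
    hm = modify_ts_hessian(h, omega=omega)
    w, v = np.linalg.eigh(h)
    wm = np.linalg.eigvalsh(hm)
    expect = np.sort(np.where(w < -q2mm.EPS_NEG, omega, w))
    assert np.allclose(np.sort(wm), expect, atol=1e-8)
    # non-negated eigenvectors untouched: difference is rank one
    diff = hm - h
    assert np.linalg.matrix_rank(diff, tol=1e-6) == 1


def test_modify_ts_hessian_rejects_second_order_saddle():
    w = np.diag([-5.0, -3.0, 1.0, 2.0])
    with pytest.raises(NotFirstOrderSaddleError):
        modify_ts_hessian(w, omega=100.0)


def test_modify_ts_hessian_identity_on_minimum():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(6, 6))
    h = a @ a.T + 1e-3 * np.eye(6)  # positive definite
    hm = modify_ts_hessian(h, omega=100.0)
    assert np.allclose(hm, h, atol=1e-8)


def test_penalty_zero_at_truth(toy_system, toy_reference):
    _, ff_true = toy_system
    assert penalty(ff_true, [toy_reference], PenaltyConfig()) < 1e-6


def test_residual_weights_scale_quadratically(toy_system, toy_reference):
    """Penalty is Σ_cls w_cls²·S_cls, so doubling one class weight adds
    three times what zeroing it removes."""
    _, ff_true = toy_system
    ff = perturb_ff(ff_true, 0.05, seed=1)
    base = PenaltyConfig()
    doubled, zeroed = dict(base.weights), dict(base.weights)
    doubled["bond"] *= 2.0
    zeroed["bond"] = 0.0
    p_base = penalty(ff, [toy_reference], base)
    p_doubled = penalty(ff, [toy_reference], PenaltyConfig(weights=doubled))
    p_zeroed = penalty(ff, [toy_reference], PenaltyConfig(weights=zeroed))
    bond_share = p_base - p_zeroed
    assert bond_share > 0
    assert p_doubled - p_base == pytest.approx(3.0 * bond_share, rel=1e-9)


def test_fit_recovers_perturbed_forming_bond(toy_system, toy_reference):
    s, ff_true = toy_system
    keys = forming_keys(s)
    ff0 = perturb_ff(ff_true, 0.2, seed=5, keys=keys)
    cfg = PenaltyConfig(theta=keys)
    res = fit(ff0, [toy_reference], cfg)
    k_key, r0_key = keys
    assert res.ff_opt.get_param(k_key) == pytest.approx(
        ff_true.get_param(k_key), rel=0.05
    )
    assert abs(res.ff_opt.get_param(r0_key) - ff_true.get_param(r0_key)) < 0.01
    assert res.penalty_trace[0] / max(res.penalty_trace[-1], 1e-300) >= 1e3
    assert all(
        b <= a + 1e-12 for a, b in zip(res.penalty_trace, res.penalty_trace[1:])
    )


def test_fit_only_touches_theta(toy_system, toy_reference):
    s, ff_true = toy_system
    keys = forming_keys(s)
    ff0 = perturb_ff(ff_true, 0.2, seed=5, keys=keys)
    res = fit(ff0, [toy_reference], PenaltyConfig(theta=keys))
    for key in ff0.param_keys():
        if key not in keys:
            assert res.ff_opt.get_param(key) == ff0.get_param(key)


def test_internal_validation_r2_near_one_at_truth(toy_system, toy_reference):
    _, ff_true = toy_system
    r2 = internal_validate(ff_true, [toy_reference], PenaltyConfig())
    for cls, value in r2.items():
        assert value > 0.98, cls
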