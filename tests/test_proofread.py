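"""Unit tests for validation statistics and stereochemical proofreading."""

import numpy as np
import pytest

from tsforge import proofread
from tsforge.proofread import (
    ValidationRecord,
    apply_corrections,
    flag_mismatches,
    mue,
    r2,
    report,
)
from tsforge.selectivity import ThermoContext, ee_to_ddg


def rec(case_id, exp_ee, exp_config, pred_ddg, tag=""):
    return ValidationRecord(
        case_id=case_id,
        ligand_id="L1",
        nucleophile_id="N1",
        exp_ee=exp_ee,
        exp_config=exp_config,
        pred_ddg=pred_ddg,
        exclusion_tag=tag,
    )


def test_record_validation():
    with pytest.raises(ValueError):
        rec("bad", 120.0, "S", 1.0)
    with pytest.raises(ValueError):
        rec("bad", 50.0, "X", 1.0)


def test_exp_ddg_sign_convention():
    tc = ThermoContext()
    s_rec = rec("a", 90.0, "S", 0.0)
    r_rec = rec("b", 90.0, "R", 0.0)
    assert s_rec.exp_ddg == pytest.approx(ee_to_ddg(90.0, tc))
    assert r_rec.exp_ddg == pytest.approx(-s_rec.exp_ddg)


def test_ee_100_clamped_with_warning():
    r = rec("a", 100.0, "S", 5.0)
    with pytest.warns(UserWarning):
        val = r.exp_ddg
    assert np.isfinite(val)
    assert val == pytest.approx(ee_to_ddg(99.9))


def test_flagging_spec_examples():
    tc = ThermoContext()
    pred_90 = ee_to_ddg(90.0, tc)  # confident S prediction
    pred_5 = ee_to_ddg(5.0, tc)  # weak S prediction
    confident_conflict = rec("c1", 90.0, "R", pred_90)
    weak_conflict = rec("c2", 90.0, "R", pred_5)
    agreeing = rec("c3", 90.0, "S", pred_90)
    assert flag_mismatches([confident_conflict, weak_conflict, agreeing]) == ["c1"]


def test_corrections_involutive_and_strict():
    records = [rec("a", 80.0, "R", 5.0), rec("b", 40.0, "S", 1.0)]
    flipped = apply_corrections(records, ["a"])
    assert flipped[0].exp_config == "S"
    assert flipped[0].exp_ddg == pytest.approx(-records[0].exp_ddg)
    assert flipped[1] == records[1]
    assert apply_corrections(flipped, ["a"]) == records
    assert apply_corrections(records, []) == records
    with pytest.raises(KeyError):
        apply_corrections(records, ["zzz"])


def test_correction_of_flagged_record_reduces_its_error():
    tc = ThermoContext()
    r = rec("a", 85.0, "R", ee_to_ddg(85.0, tc))  # predicted +, reported R
    assert flag_mismatches([r]) == ["a"]
    (fixed,) = apply_corrections([r], ["a"])
    assert abs(fixed.pred_ddg - fixed.exp_ddg) < abs(r.pred_ddg - r.exp_ddg)


def test_mue_r2_oracles():
    records = [rec("a", 50.0, "S", 3.0), rec("b", 70.0, "R", -6.0), rec("c", 10.0, "S", 1.0)]
    exp = np.array([r.exp_ddg for r in records])
    pred = np.array([r.pred_ddg for r in records])
    assert mue(records) == pytest.approx(np.abs(pred - exp).mean())
    assert r2(records) == pytest.approx(np.corrcoef(pred, exp)[0, 1] ** 2)
    assert r2(records[:1]) is None
    same = [rec("a", 50.0, "S", 2.0), rec("b", 60.0, "S", 2.0)]
    assert r2(same) is None  # zero predictor variance
    with pytest.raises(ValueError):
        mue([])


def test_report_excludes_tags():
    records = [
        rec("a", 50.0, "S", 3.0),
        rec("b", 70.0, "R", -6.0),
        rec("c", 80.0, "S", 4.0, tag="indphox"),
    ]
    rep_all = report(records)
    rep_sub = report(records, exclude_tags=("indphox",))
    assert rep_all.n_total == 3 and rep_all.n_excluded == 0
    assert rep_sub.n_total == 2 and rep_sub.n_excluded == 1
    with pytest.raises(ValueError):
        report([rec("x", 10.0, "S", 1.0, tag="t")], exclude_tags=("t",))


def test_perfect_predictions_give_zero_mue_unit_r2():
    tc = ThermoContext()
    records = [
        rec("a", 30.0, "S", ee_to_ddg(30.0, tc)),
        rec("b", 60.0, "R", ee_to_ddg(-60.0, tc)),
        rec("c", 90.0, "S", ee_to_ddg(90.0, tc)),
    ]
    rep = report(records)
    assert rep.initial.mue == pytest.approx(0.0, abs=1e-12)
    assert rep.initial.r2 == pytest.approx(1.0)
    assert rep.n_flagged == 0


def test_csv_roundtrip(tmp_path, validation_records):
    path = tmp_path / "table.csv"
    proofread.save_table(path, validation_records)
    back = proofread.load_table(path)
    assert len(back) == len(validation_records)
    for a, b in zip(back, validation_records):
        assert a.case_id == b.case_id
        assert a.exp_config == b.exp_config
        assert a.exp_ee == pytest.approx(b.exp_ee)
        assert a.pred_ddg == pytest.approx(b.pred_ddg)
        assert a.exclusion_tag == b.exclusion_tag
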