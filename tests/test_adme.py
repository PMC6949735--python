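"""Drug-likeness scoring, half-life regression and the three-axis screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herbnet.adme import (HL_DESCRIPTOR_NAMES, HLModel, ScreeningCriteria,
                          load_default_criteria, load_hl_model, predict_hl,
                          retention_rate, screen, tanimoto_dl)
from herbnet.errors import HerbnetError
from herbnet.io_tables import IngredientRecord

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)
vectors = st.integers(min_value=1, max_value=8).flatmap(
    lambda d: st.tuples(
        st.lists(finite, min_size=d, max_size=d),
        st.lists(finite, min_size=d, max_size=d)))


class TestTanimotoDL:
    def test_identical_nonzero_vectors_score_one(self):
        assert tanimoto_dl([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self):
        assert tanimoto_dl([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_worked_example(self):
        # (1,2)·(2,1) = 4; ‖x‖²+‖y‖²−x·y = 5+5−4 = 6
        assert tanimoto_dl([1, 2], [2, 1]) == pytest.approx(4 / 6)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(vectors)
    def test_symmetry(self, xy):
        x, y = xy
        if not (any(x) or any(y)):
            return
        assert tanimoto_dl(x, y) == pytest.approx(tanimoto_dl(y, x))

    def test_not_scale_invariant(self):
        # documented behaviour of the continuous form, not a defect
        assert tanimoto_dl([2, 4], [2, 1]) != pytest.approx(tanimoto_dl([1, 2], [2, 1]))

    def test_dimension_mismatch_and_zero_vectors_raise(self):
        with pytest.raises(HerbnetError, match="mismatch"):
            tanimoto_dl([1, 2], [1, 2, 3])
        with pytest.raises(HerbnetError, match="zero"):
            tanimoto_dl([0, 0], [0, 0])


class TestPredictHL:
    def test_all_zero_descriptors_give_intercept(self):
        d = {k: 0.0 for k in HL_DESCRIPTOR_NAMES}
        assert predict_hl(d) == pytest.approx(13.310)

    def test_single_term(self):
        d = {k: 0.0 for k in HL_DESCRIPTOR_NAMES}
        d["DDr09"] = 1.0
        assert predict_hl(d) == pytest.approx(13.310 + 0.053)

    def test_missing_descriptor_named(self):
        d = {k: 0.0 for k in HL_DESCRIPTOR_NAMES if k != "JGI6"}
        with pytest.raises(HerbnetError, match="JGI6"):
            predict_hl(d)

    def test_model_requires_exactly_eight_descriptors(self):
        with pytest.raises(HerbnetError):
            HLModel(intercept=0.0, coef={"nArCO": 1.0})

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(finite, min_size=8, max_size=8),
           st.lists(finite, min_size=8, max_size=8))
    def test_affine_identity(self, a, b):
        da = dict(zip(HL_DESCRIPTOR_NAMES, a))
        db = dict(zip(HL_DESCRIPTOR_NAMES, b))
        dab = {k: da[k] + db[k] for k in HL_DESCRIPTOR_NAMES}
        model = load_hl_model()
        lhs = predict_hl(da, model) + predict_hl(db, model) - model.intercept
        assert lhs == pytest.approx(predict_hl(dab, model), abs=1e-6)

    def test_matches_dot_product_oracle(self):
        model = load_hl_model()
        rng = np.random.default_rng(42)
        names = list(HL_DESCRIPTOR_NAMES)
        for _ in range(200):
            vals = rng.normal(size=8)
            oracle = model.intercept + sum(
                model.coef[n] * v for n, v in zip(names, vals))
            assert predict_hl(dict(zip(names, vals)), model) == pytest.approx(
                oracle, abs=1e-9)


def _rec(iid, ob, dl, hl):
    return IngredientRecord(ingredient_id=iid, name=iid, herb="h",
                            ob=ob, dl=dl, hl=hl)


class TestScreen:
    def test_berberine_passes(self):
        report = screen([_rec("mol05", 36.86, 0.78, 6.57)])
        assert report.rows[0].passed

    def test_quercetin_fails_on_half_life(self):
        report = screen([_rec("mol01", 46.43, 0.28, 14.40)])
        row = report.rows[0]
        assert not row.passed
        assert row.failed == ("HL",)
        assert row.reasons["HL"] == "above"

    def test_bounds_are_inclusive(self):
        report = screen([_rec("edge", 30.0, 0.18, 4.0),
                         _rec("edge2", 30.0, 0.18, 8.0)])
        assert all(r.passed for r in report.rows)

    def test_missing_value_fails_with_reason_missing(self):
        report = screen([_rec("m", None, 0.5, 5.0)])
        assert report.rows[0].failed == ("OB",)
        assert report.rows[0].reasons["OB"] == "missing"

    def test_partition_invariant(self, table1_records):
        report = screen(table1_records)
        assert report.n_pass + len(report.failed) == report.n_total
        for row in report.rows:
            assert row.passed == (len(row.failed) == 0)

    def test_fixture_strict_pass_matches_row_scan_oracle(self, table1_records):
        """Independent row scan of the reference catalogue: 18 strict passes."""
        oracle_pass = [r.ingredient_id for r in table1_records
                       if r.ob >= 30 and r.dl >= 0.18 and 4 <= r.hl <= 8]
        report = screen(table1_records)
        assert [r.ingredient_id for r in report.passed] == oracle_pass
        assert len(oracle_pass) == 18

    def test_noncompliant_rows_are_flagged_with_reasons(self, table1_records):
        report = screen(table1_records)
        for row in report.failed:
            assert row.failed  # every non-pass names at least one criterion
            assert set(row.failed) <= {"OB", "DL", "HL"}

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ob_min=st.floats(min_value=0, max_value=30),
           dl_min=st.floats(min_value=0, max_value=0.18),
           hl_min=st.floats(min_value=0, max_value=4),
           hl_max=st.floats(min_value=8, max_value=30))
    def test_relaxing_thresholds_never_shrinks_pass_set(
            self, ob_min, dl_min, hl_min, hl_max, table1_records):
        base = {r.ingredient_id for r in screen(table1_records).passed}
        relaxed = ScreeningCriteria(ob_min=ob_min, dl_min=dl_min,
                                    hl_min=hl_min, hl_max=hl_max)
        wider = {r.ingredient_id for r in screen(table1_records, relaxed).passed}
        assert base <= wider

    def test_default_criteria_fixture(self):
        c = load_default_criteria()
        assert (c.ob_min, c.dl_min, c.hl_min, c.hl_max) == (30.0, 0.18, 4.0, 8.0)

    def test_invalid_criteria(self):
        with pytest.raises(HerbnetError):
            ScreeningCriteria(hl_min=9, hl_max=8)


class TestRetentionRate:
    @pytest.mark.parametrize("n_pass,n_total,expected", [
        (41, 382, 10.73),
        (0, 10, 0.00),
        (382, 382, 100.00),
        (1, 3, 33.33),
        (1, 800, 0.13),  # 0.125 rounds half-up
    ])
    def test_half_up_two_decimals(self, n_pass, n_total, expected):
        assert retention_rate(n_pass, n_total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(HerbnetError):
            retention_rate(0, 0)
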