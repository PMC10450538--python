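"""Case-only estimators: closed forms, Wald intervals, ML and Poisson
cross-checks, and the full analysis table."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tweetsurge import (
    CaseOnlyTable,
    CharacteristicCoding,
    ZeroCellError,
    caseonly_or_binary,
    caseonly_rrr_multinomial,
    crosstab,
    poisson_oracle,
    run_analysis,
)
from tweetsurge.caseonly import Z_95

from conftest import make_calendar

SEX = CharacteristicCoding("sex", ("female", "male"), "female")


def table2x2(n00, n01, n10, n11):
    """counts[e][j]: e in {non-surge, surge}, j in {female, male}."""
    return CaseOnlyTable("sex", ("female", "male"), "female", [[n00, n01], [n10, n11]])


class TestCrosstab:
    def test_each_cell_once(self, four_cell_rows):
        t = crosstab(four_cell_rows, SEX)
        assert np.array_equal(t.counts, [[1, 1], [1, 1]])
        assert t.total == 4

    def test_empty_input_all_zero(self):
        t = crosstab(pd.DataFrame(columns=["exposed", "sex"]), SEX)
        assert np.array_equal(t.counts, np.zeros((2, 2)))

    def test_hand_counted_2x3(self):
        coding = CharacteristicCoding("occ", ("a", "b", "c"), "a")
        rows = pd.DataFrame(
            {
                "exposed": [False] * 4 + [True] * 3,
                "occ": ["a", "a", "b", "c", "b", "b", "c"],
            }
        )
        t = crosstab(rows, coding)
        assert np.array_equal(t.counts, [[2, 1, 1], [0, 2, 1]])

    def test_unknown_level_rejected(self):
        rows = pd.DataFrame({"exposed": [True], "sex": ["unknown"]})
        with pytest.raises(ValueError, match="unknown"):
            crosstab(rows, SEX)


class TestBinaryOr:
    def test_cross_product_is_four(self):
        est = caseonly_or_binary(table2x2(40, 20, 5, 10))
        assert est.estimate == pytest.approx(4.0, rel=1e-12)
        assert est.level == "male"

    def test_equal_cells_give_unity_and_ci_straddles_one(self):
        est = caseonly_or_binary(table2x2(7, 7, 7, 7))
        assert est.estimate == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high
        assert not est.significant

    def test_hand_computed_wald_interval(self):
        # log4 -/+ z * sqrt(1/40+1/20+1/5+1/10), z = 1.959964
        est = caseonly_or_binary(table2x2(40, 20, 5, 10))
        se = math.sqrt(1 / 40 + 1 / 20 + 1 / 5 + 1 / 10)
        assert est.se_log == pytest.approx(se, rel=1e-12)
        assert est.ci_low == pytest.approx(math.exp(math.log(4) - Z_95 * se), rel=1e-12)
        assert est.ci_high == pytest.approx(math.exp(math.log(4) + Z_95 * se), rel=1e-12)
        # frozen values from the arithmetic above
        assert est.ci_low == pytest.approx(1.20450, abs=1e-4)
        assert est.ci_high == pytest.approx(13.28350, abs=2e-4)

    def test_zero_cell_raises_unless_corrected(self):
        with pytest.raises(ZeroCellError, match="zero cell"):
            caseonly_or_binary(table2x2(40, 20, 0, 10))
        est = caseonly_or_binary(table2x2(40, 20, 0, 10), correction=True)
        assert est.corrected
        expected = (10.5 * 40.5) / (0.5 * 20.5)
        assert est.estimate == pytest.approx(expected, rel=1e-9)

    def test_needs_two_levels(self):
        t = CaseOnlyTable("occ", ("a", "b", "c"), "a", np.ones((2, 3)))
        with pytest.raises(ValueError, match="2x2"):
            caseonly_or_binary(t)


class TestMultinomialRrr:
    def test_hand_computed_cross_products(self):
        # base column 100/100, A 50/60, B 80/40:
        # RRR_A = (60*100)/(50*100) = 1.2, RRR_B = (40*100)/(80*100) = 0.5
        t = CaseOnlyTable(
            "occ", ("base", "A", "B"), "base", [[100, 50, 80], [100, 60, 40]]
        )
        ests = {e.level: e for e in caseonly_rrr_multinomial(t)}
        assert ests["A"].estimate == pytest.approx(1.2, rel=1e-9)
        assert ests["B"].estimate == pytest.approx(0.5, rel=1e-9)
        assert ests["A"].se_log == pytest.approx(
            math.sqrt(1 / 60 + 1 / 50 + 1 / 100 + 1 / 100), rel=1e-12
        )

    def test_binary_reduction_matches_or(self):
        t = table2x2(40, 20, 5, 10)
        (rrr,) = caseonly_rrr_multinomial(t)
        est = caseonly_or_binary(t)
        assert rrr.estimate == pytest.approx(est.estimate, rel=1e-12)
        assert rrr.se_log == pytest.approx(est.se_log, rel=1e-12)

    def test_proportional_columns_give_unity(self):
        t = CaseOnlyTable(
            "occ", ("base", "A", "B"), "base", [[100, 50, 20], [200, 100, 40]]
        )
        for est in caseonly_rrr_multinomial(t):
            assert est.estimate == pytest.approx(1.0, rel=1e-9)

    def test_zero_cell_in_involved_column(self):
        t = CaseOnlyTable("occ", ("base", "A"), "base", [[100, 0], [100, 10]])
        with pytest.raises(ZeroCellError):
            caseonly_rrr_multinomial(t)
        ests = caseonly_rrr_multinomial(t, correction=True)
        assert ests[0].corrected


class TestPoissonOracle:
    def test_saturated_identity_on_example(self):
        est = poisson_oracle(table2x2(40, 20, 5, 10))
        assert est.estimate == pytest.approx(4.0, rel=1e-6)
        assert est.estimator == "poisson_oracle"

    def test_oracle_se_equals_closed_form(self):
        t = table2x2(40, 20, 5, 10)
        assert poisson_oracle(t).se_log == pytest.approx(
            caseonly_or_binary(t).se_log, rel=1e-5
        )

    def test_from_rows(self, four_cell_rows):
        rows = pd.concat([four_cell_rows] * 5, ignore_index=True)
        est = poisson_oracle(rows, SEX)
        assert est.estimate == pytest.approx(1.0, rel=1e-6)

    @given(st.lists(st.integers(1, 400), min_size=4, max_size=4))
    @settings(max_examples=40)
    def test_oracle_equals_closed_form_on_random_tables(self, cells):
        t = table2x2(*cells)
        closed = caseonly_or_binary(t, verify_ml=False)
        oracle = poisson_oracle(t)
        assert oracle.estimate == pytest.approx(closed.estimate, rel=1e-6)


class TestMlIdentity:
    @given(st.lists(st.integers(1, 300), min_size=4, max_size=4))
    @settings(max_examples=25)
    def test_binary_logistic_agrees(self, cells):
        # verify_ml raises if the ML fit deviates by > 1e-6 relative
        caseonly_or_binary(table2x2(*cells), verify_ml=True)

    @given(st.lists(st.integers(1, 60), min_size=8, max_size=8))
    @settings(max_examples=10)
    def test_multinomial_logistic_agrees(self, cells):
        t = CaseOnlyTable(
            "occ",
            ("base", "A", "B", "C"),
            "base",
            np.asarray(cells, dtype=float).reshape(2, 4),
        )
        caseonly_rrr_multinomial(t, verify_ml=True)


class TestRunAnalysis:
    @staticmethod
    def rows_records(n_per_cell=25):
        """Records whose lag-3 merge reproduces a known 2x2 pattern."""
        exposed = np.zeros(40)
        exposed[10:20] = 1.0
        cal = make_calendar(exposed)
        dates, sexes = [], []
        # deaths on days whose lag-3 date is exposed vs not
        for day, e in (("2011-01-15", 1), ("2011-02-05", 0)):
            for sex, n in (("female", n_per_cell), ("male", 2 * n_per_cell if e else n_per_cell)):
                dates += [day] * n
                sexes += [sex] * n
        n = len(dates)
        return cal, pd.DataFrame(
            {
                "date": pd.to_datetime(dates),
                "age": [30] * n,
                "sex": sexes,
                "occupation": ["corporate"] * n,
                "marital_status": ["married"] * n,
                "area": ["urban"] * n,
                "icd10": ["X60"] * n,
            }
        )

    def test_single_lag_single_binary_characteristic(self):
        cal, records = self.rows_records()
        out = run_analysis(records, cal, lags=[3], codings=[SEX])
        assert len(out) == 1
        row = out.iloc[0]
        assert row["estimate"] == pytest.approx(2.0, rel=1e-9)
        assert row["lag_days"] == 3 and row["level"] == "male"
        assert row["ci_low"] <= row["estimate"] <= row["ci_high"]

    def test_empty_codings_give_empty_table(self):
        cal, records = self.rows_records()
        out = run_analysis(records, cal, lags=[3], codings=[])
        assert out.empty
        assert "estimate" in out.columns

    def test_mode_filters_causes(self):
        cal, records = self.rows_records()
        records.loc[records.index[::2], "icd10"] = "W10"  # every other row
        out = run_analysis(records, cal, lags=[3], codings=[SEX], mode="unexpected")
        assert (out["n_rows"] < len(records)).all()

    def test_errors_tagged_with_lag_and_characteristic(self):
        cal, records = self.rows_records()
        records["sex"] = "male"  # empty female column -> zero cells
        with pytest.raises(ZeroCellError, match="lag=3.*sex"):
            run_analysis(records, cal, lags=[3], codings=[SEX])

    def test_empty_lags_rejected(self):
        cal, records = self.rows_records()
        with pytest.raises(ValueError, match="lags"):
            run_analysis(records, cal, lags=[], codings=[SEX])

    def test_significance_flag_matches_p_value(self):
        cal, records = self.rows_records(200)
        out = run_analysis(records, cal, lags=[3], codings=[SEX])
        assert bool(out["significant"].iloc[0]) == (out["p_value"].iloc[0] < 0.05)
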