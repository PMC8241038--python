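"""Yearly aggregation, normalization, stratum medians and the
pure-practice comparison, checked against the published summary tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pathworkload as pw
from pathworkload.aggregate import StratumSummary
from pathworkload.errors import NormalizationError


@pytest.fixture(scope="module")
def published_yearly() -> pd.DataFrame:
    return pw.load_published_yearly_totals()


@pytest.fixture(scope="module")
def published_medians() -> list[StratumSummary]:
    return pw.load_published_stratum_medians()


class TestAggregateYearly:
    def test_single_case_row_equals_case(self, records):
        one = records.iloc[[0]]
        row = pw.aggregate_yearly(one).iloc[0]
        assert row["l4e_total"] == one.iloc[0]["l4e"]
        assert row["case_total"] == 1
        assert row["report_lines_total"] == (
            one.iloc[0]["dx_lines"] + one.iloc[0]["micro_lines"] + one.iloc[0]["ccs_lines"]
        )

    def test_totals_equal_ground_truth_sums(self, corpus, records):
        _, _, truths = corpus
        yearly = pw.aggregate_yearly(records)
        for _, row in yearly.iterrows():
            year_truths = [t for t in truths if t.year == row["year"]]
            assert row["case_total"] == len(year_truths)
            assert row["blocks_total"] == sum(t.block_count for t in year_truths)
            assert row["ihc_total"] == sum(min(t.hr_count, 99) for t in year_truths)
            assert row["special_stain_total"] == sum(t.ss_count for t in year_truths)
            assert row["report_lines_total"] == sum(
                t.dx_lines + t.micro_lines + t.ccs_lines for t in year_truths
            )

    def test_permutation_invariant(self, records):
        shuffled = records.sample(frac=1.0, random_state=0)
        a = pw.aggregate_yearly(records).reset_index(drop=True)
        b = pw.aggregate_yearly(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_published_2019_line_sum(self):
        """The published 2019 section lines total equals Dx+Micro+CCS."""
        lines = pw.load_published_report_lines()
        row = lines[lines["year"] == 2019].iloc[0]
        assert row["dx"] + row["micro"] + row["ccs"] == 723175 == row["sum"]
        assert (lines["dx"] + lines["micro"] + lines["ccs"] == lines["sum"]).all()


class TestNormalizeSeries:
    def test_reference_row_is_all_ones(self, published_yearly):
        norm = pw.normalize_series(published_yearly, 2011)
        ref = norm[norm["year"] == 2011].iloc[0]
        assert all(ref[c] == 1.0 for c in norm.columns if c != "year")

    def test_published_blocks_normalization(self, published_yearly):
        norm = pw.normalize_series(published_yearly, 2011)
        blocks_2019 = norm.loc[norm["year"] == 2019, "blocks"].iloc[0]
        assert round(blocks_2019, 3) == 1.201  # +20% over the period

    def test_constant_series_stays_one(self):
        df = pd.DataFrame({"year": [2011, 2012], "m": [5.0, 5.0]})
        norm = pw.normalize_series(df, 2011)
        assert (norm["m"] == 1.0).all()

    def test_denormalization_recovers_table(self, published_yearly):
        norm = pw.normalize_series(published_yearly, 2011)
        ref = published_yearly[published_yearly["year"] == 2011].iloc[0]
        for col in ("l4e", "blocks", "cases"):
            back = norm[col] * ref[col]
            assert np.allclose(back, published_yearly[col])

    def test_zero_reference_metric_raises(self):
        df = pd.DataFrame({"year": [2011, 2012], "m": [0.0, 3.0]})
        with pytest.raises(NormalizationError, match="m"):
            pw.normalize_series(df, 2011)

    def test_missing_reference_year_raises(self, published_yearly):
        with pytest.raises(ValueError, match="1999"):
            pw.normalize_series(published_yearly, 1999)


class TestPercentChange:
    @pytest.mark.parametrize("start, end, expected", [
        (66056, 61962, -6),       # cases over the period
        (165276.0, 203893.6, 23), # L4E units
        (5, 5, 0),
        (100, 102.5, 3),          # half rounds away from zero
        (100, 97.5, -3),
    ])
    def test_rounded_percent(self, start, end, expected):
        assert pw.percent_change(start, end) == expected

    def test_nonpositive_start_raises(self):
        with pytest.raises(ValueError):
            pw.percent_change(0, 5)

    def test_agrees_with_normalized_ratio(self, published_yearly):
        norm = pw.normalize_series(published_yearly, 2011)
        for col in ("l4e", "w2q", "blocks", "cases", "sob_fees"):
            ratio = norm.loc[norm["year"] == 2019, col].iloc[0]
            start = published_yearly.loc[published_yearly["year"] == 2011, col].iloc[0]
            end = published_yearly.loc[published_yearly["year"] == 2019, col].iloc[0]
            assert pw.percent_change(start, end) == round(100 * (ratio - 1))


class TestStratumMedians:
    def test_single_case_stratum(self, records):
        one = records[records["stratum"] == "L866"].iloc[[0]]
        (summ,) = pw.stratum_medians(one)
        assert summ.median_l4e == one.iloc[0]["l4e"]
        assert summ.median_fee == one.iloc[0]["fee"]

    def test_odd_stratum_matches_sort_and_pick_middle(self, records):
        sub = records[records["stratum"] == "L865"].iloc[:101]
        (summ,) = pw.stratum_medians(sub)
        middle = sorted(sub["l4e"])[50]
        assert summ.median_l4e == middle


class TestPurePracticeComparison:
    def test_published_worked_examples(self, published_medians):
        cmp_ = pw.pure_practice_comparison(published_medians)
        l864 = cmp_.per_stratum["L864"]
        # 7,500 W2Q x $97.30 / 2.00 W2Q
        assert l864.fees_at_w2q_target == pytest.approx(364875.00)
        # 7,500 W2Q x 1.8525 L4E / 2.00 W2Q
        assert l864.l4e_equiv_of_w2q_target == pytest.approx(6946.875)

    def test_identical_medians_symmetric(self):
        same = [StratumSummary("A", 2.0, 3.0, 100.0),
                StratumSummary("B", 2.0, 3.0, 100.0)]
        cmp_ = pw.pure_practice_comparison(same)
        pair = cmp_.pairwise("A", "B")
        assert pair["fee_diff_at_w2q_target"] == 0.0
        assert pair["fee_ratio_at_w2q_target"] == 1.0
        assert pair["l4e_equiv_ratio"] == 1.0

    def test_zero_median_divisor_raises(self):
        with pytest.raises(ValueError, match="zero median"):
            pw.pure_practice_comparison([StratumSummary("A", 0.0, 1.0, 10.0)])


class TestFeePerUnit:
    def test_published_endpoints(self, published_yearly):
        table = published_yearly.rename(columns={
            "l4e": "l4e_total", "sob_fees": "sob_fees_total"})
        trend = pw.fee_per_unit_trend(table)
        assert round(trend.loc[2011], 2) == 40.94
        assert round(trend.loc[2019], 2) == 37.65

    def test_zero_l4e_total_raises(self):
        df = pd.DataFrame({"year": [2011], "l4e_total": [0.0],
                           "sob_fees_total": [10.0]})
        with pytest.raises(ValueError, match="2011"):
            pw.fee_per_unit_trend(df)

    def test_zero_fees_give_zero(self):
        df = pd.DataFrame({"year": [2011], "l4e_total": [10.0],
                           "sob_fees_total": [0.0]})
        assert (pw.fee_per_unit_trend(df) == 0).all()

    def test_per_stratum_breakdown(self, records):
        by = pw.fee_per_l4e_by_stratum(records)
        assert set(by.columns) == {"year", "stratum", "fee_per_l4e"}
        assert (by["fee_per_l4e"] >= 0).all()
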