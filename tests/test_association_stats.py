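"""Contingency tables, independence tests and odds ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hncmeta import TestMethod as Method
from hncmeta import (
    ContingencyTable,
    MentionCategory,
    chi_square_test,
    choose_test,
    collapse_mention,
    crosstab,
    fisher_exact,
    odds_ratio,
    run_test,
)
from hncmeta.reference import (
    MENTION_BY_ENROLMENT,
    MENTION_BY_PHASE,
    MENTION_BY_STUDY_TYPE,
    STUDY_TYPE_BY_CATEGORY,
)

from conftest import fisher_enumeration, pearson_2x2_closed_form


def table(cells) -> ContingencyTable:
    cells = np.asarray(cells)
    return ContingencyTable(
        row_labels=[f"r{i}" for i in range(cells.shape[0])],
        col_labels=[f"c{j}" for j in range(cells.shape[1])],
        counts=cells,
    )


class TestContingencyTable:
    def test_margins(self):
        t = table([[1, 2], [3, 4]])
        assert t.row_margins.tolist() == [3, 7]
        assert t.col_margins.tolist() == [4, 6]
        assert t.total == 10

    def test_rejects_negative_and_fractional(self):
        with pytest.raises(ValueError):
            table([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            table([[1.5, 1], [0, 2]])


class TestChiSquare:
    def test_uniform_table_statistic_zero(self):
        result = chi_square_test(table([[10, 10], [10, 10]]))
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # all expected cells are 15: statistic = 4 * 25/15 = 20/3
        result = chi_square_test(table([[20, 10], [10, 20]]))
        assert result.statistic == pytest.approx(20 / 3)
        assert result.p_value == pytest.approx(0.009823, abs=1e-6)
        assert result.df == 1

    def test_independent_outer_product_is_zero(self):
        rows, cols = np.array([30, 60]), np.array([10, 20, 30])
        counts = np.outer(rows, cols) // 60
        result = chi_square_test(table(counts))
        assert result.statistic == pytest.approx(0.0)
        assert result.df == 2

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test(table([[0, 0], [5, 5]]))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_2x2_statistic_equals_closed_form(self, cells):
        a, b, c, d = cells
        result = chi_square_test(table([[a, b], [c, d]]))
        assert result.statistic == pytest.approx(
            pearson_2x2_closed_form(a, b, c, d), rel=1e-12
        )


class TestFisher:
    def test_modal_table_p_one(self):
        assert fisher_exact(table([[5, 5], [5, 5]])).p_value == pytest.approx(1.0)

    def test_extreme_table_enumeration(self):
        # both extreme tables of margins (5,5)/(5,5): p = 2/C(10,5)
        result = fisher_exact(table([[0, 5], [5, 0]]))
        assert result.p_value == pytest.approx(2 / 252)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 10)] * 4))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        result = fisher_exact(table([[a, b], [c, d]]))
        assert result.p_value == pytest.approx(
            fisher_enumeration(a, b, c, d), abs=1e-12
        )

    def test_non_2x2_falls_back_to_pearson(self):
        result = fisher_exact(table([[5, 5, 5], [5, 5, 5]]))
        assert result.method is Method.PEARSON_CHI2


class TestChooseTest:
    @pytest.mark.parametrize(
        ("cells", "expected"),
        [
            ([[2, 3], [3, 2]], Method.FISHER_EXACT),  # expected counts 2.5
            ([[100, 100], [100, 100]], Method.PEARSON_CHI2),
            ([[2, 3, 2], [3, 2, 3]], Method.PEARSON_CHI2),  # small but not 2x2
        ],
    )
    def test_selection_rule(self, cells, expected):
        assert choose_test(table(cells)) is expected

    def test_run_test_dispatches(self):
        assert run_test(table([[2, 3], [3, 2]])).method is Method.FISHER_EXACT
        assert run_test(table([[100, 100], [100, 100]])).method is Method.PEARSON_CHI2


class TestCollapse:
    @pytest.mark.parametrize(
        ("category", "expected"),
        [
            (MentionCategory.ANALYTICAL, "MENTION"),
            (MentionCategory.RECRUITMENT_ONLY, "MENTION"),
            (MentionCategory.NO_MENTION, "NO_MENTION"),
        ],
    )
    def test_mapping(self, category, expected):
        assert collapse_mention(category) == expected
        assert collapse_mention(category.value) == expected


class TestOddsRatio:
    def test_symmetric_table_is_one(self):
        for k in (1, 7, 100):
            assert odds_ratio(table([[k, k], [k, k]])).estimate == pytest.approx(1.0)

    def test_reference_cells_reproduce_reported_estimates(self):
        """The three reported OR/CI triples recompute from the table cells."""
        expected = {
            "study_type": (MENTION_BY_STUDY_TYPE, 5.76, 4.29, 7.72),
            "enrolment": (MENTION_BY_ENROLMENT, 1.29, 1.04, 1.60),
            "phase": (MENTION_BY_PHASE, 0.63, 0.42, 0.94),
        }
        for name, (tab, or_, lo, hi) in expected.items():
            result = odds_ratio(tab)
            assert round(result.estimate, 2) == or_, name
            assert round(result.ci_low, 2) == lo, name
            assert round(result.ci_high, 2) == hi, name

    def test_haldane_correction_on_single_zero(self):
        result = odds_ratio(table([[0, 5], [5, 5]]))
        assert result.haldane_corrected
        assert result.estimate == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))

    def test_zero_line_undefined(self):
        with pytest.raises(ValueError):
            odds_ratio(table([[0, 0], [5, 5]]))
        with pytest.raises(ValueError):
            odds_ratio(table([[0, 5], [0, 5]]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_swap_identities(self, cells):
        a, b, c, d = cells
        base = odds_ratio(table([[a, b], [c, d]])).estimate
        # swapping both rows and both columns leaves the estimate unchanged
        double = odds_ratio(table([[d, c], [b, a]])).estimate
        assert double == pytest.approx(base, rel=1e-12)
        # swapping rows alone inverts it exactly
        rows = odds_ratio(table([[c, d], [a, b]])).estimate
        assert rows == pytest.approx(1 / base, rel=1e-12)

    def test_ci_is_wald_on_log_scale(self):
        result = odds_ratio(table([[20, 10], [10, 20]]))
        se = np.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
        assert result.log_se == pytest.approx(se)
        assert result.ci_low <= result.estimate <= result.ci_high

    def test_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        t2 = sm.Table2x2(MENTION_BY_STUDY_TYPE.counts)
        result = odds_ratio(MENTION_BY_STUDY_TYPE)
        assert result.estimate == pytest.approx(t2.oddsratio)
        lo, hi = t2.oddsratio_confint(0.05)
        assert result.ci_low == pytest.approx(lo, rel=1e-6)
        assert result.ci_high == pytest.approx(hi, rel=1e-6)


class TestCrosstab:
    def labels_frame(self):
        return pd.DataFrame(
            {
                "nct_id": [f"NCT{i:08d}" for i in range(8)],
                "study_type": ["INTERVENTIONAL"] * 5 + ["OBSERVATIONAL"] * 3,
                "sg_category": ["ANALYTICAL", "NO_MENTION", "RECRUITMENT_ONLY",
                                "NO_MENTION", "ANALYTICAL", "NO_MENTION",
                                "RECRUITMENT_ONLY", "NO_MENTION"],
                "control_class": ["CONTROLLED"] * 4 + ["UNCONTROLLED"] * 4,
            }
        )

    def test_counts_every_study_once(self):
        t = crosstab(self.labels_frame(), "study_type", "sg_category")
        assert t.total == 8

    def test_planted_counts_recovered(self):
        t = crosstab(
            self.labels_frame(), "study_type", "sg_category",
            row_order=["INTERVENTIONAL", "OBSERVATIONAL"],
            col_order=["ANALYTICAL", "RECRUITMENT_ONLY", "NO_MENTION"],
        )
        assert t.counts.tolist() == [[2, 1, 2], [0, 1, 2]]

    def test_filter_restricts_population(self):
        frame = self.labels_frame()
        t = crosstab(frame, "study_type", "sg_category",
                     filter=frame["control_class"] == "CONTROLLED")
        assert t.total == 4

    def test_unknown_variable_is_configuration_error(self):
        with pytest.raises(KeyError):
            crosstab(self.labels_frame(), "nope", "sg_category")


def test_category_partition_sums_to_cohort():
    """The three S/G categories partition the reference cohort."""
    assert STUDY_TYPE_BY_CATEGORY.total == 1672
    assert STUDY_TYPE_BY_CATEGORY.col_margins.tolist() == [89, 943, 640]
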