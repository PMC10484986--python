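"""Contingency tables, chi-square / Fisher tests and odds ratios.

The analysis cross-tabulates each study label against the S/G mention
category (or against HPV mention) and tests independence with Pearson's
chi-square, falling back to Fisher's exact test on 2x2 tables with any
expected cell below 5.  For 2x2 tables built from the mention-collapsed
categories (some mention vs no mention) the association strength is the
odds ratio with a 95% Wald confidence interval on the log scale,

    OR = ad / bc,   SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d),
    CI = exp(log OR +/- 1.96 SE),

with the Haldane-Anscombe 0.5 correction (and a flag) when a single cell
is zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mention_tagging import MentionCategory

log = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class TestMethod(str, Enum):
    PEARSON_CHI2 = "PEARSON_CHI2"
    FISHER_EXACT = "FISHER_EXACT"


@dataclass
class ContingencyTable:
    """A labeled r x c table of nonnegative integer counts."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be nonnegative integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def expected(self) -> np.ndarray:
        return np.outer(self.row_margins, self.col_margins) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ContingencyTable":
        return cls(
            row_labels=[str(i) for i in frame.index],
            col_labels=[str(c) for c in frame.columns],
            counts=frame.to_numpy(),
        )


@dataclass
class TestResult:
    method: TestMethod
    p_value: float
    statistic: float | None = None
    df: int | None = None


@dataclass
class OddsRatioResult:
    """Cross-product odds ratio with its Wald 95% CI and orientation."""

    estimate: float
    log_se: float
    ci_low: float
    ci_high: float
    reference_row: str
    reference_col: str
    haldane_corrected: bool = False


def crosstab(
    labels_table: pd.DataFrame,
    row_var: str,
    col_var: str,
    filter: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate two label columns, counting every study once.

    ``filter`` optionally restricts the population (callable on the table
    or boolean mask).  Explicit row/col orders drop absent levels.
    """
    for var in (row_var, col_var):
        if var not in labels_table.columns:
            raise KeyError(f"unknown variable {var!r} in labels table")
    df = labels_table
    if filter is not None:
        mask = filter(df) if callable(filter) else filter
        df = df[np.asarray(mask, dtype=bool)]
    frame = pd.crosstab(df[row_var], df[col_var])
    if row_order is not None:
        frame = frame.reindex([r for r in row_order if r in frame.index])
    else:
        frame = frame.sort_index()
    if col_order is not None:
        frame = frame.reindex(columns=[c for c in col_order if c in frame.columns])
    else:
        frame = frame.sort_index(axis=1)
    return ContingencyTable.from_frame(frame.fillna(0).astype(int))


def _check_testable(table: ContingencyTable) -> None:
    r, c = table.shape
    if r < 2 or c < 2:
        raise ValueError(f"need at least a 2x2 table, got {r}x{c}")
    if table.total == 0:
        raise ValueError("table is empty")
    if np.any(table.row_margins == 0):
        empty = [table.row_labels[i] for i in np.flatnonzero(table.row_margins == 0)]
        raise ValueError(f"degenerate table: empty row margin(s) {empty}")
    if np.any(table.col_margins == 0):
        empty = [table.col_labels[i] for i in np.flatnonzero(table.col_margins == 0)]
        raise ValueError(f"degenerate table: empty column margin(s) {empty}")


def chi_square_test(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    _check_testable(table)
    statistic, p, df, _ = stats.chi2_contingency(table.counts, correction=False)
    return TestResult(
        method=TestMethod.PEARSON_CHI2, p_value=float(p), statistic=float(statistic), df=int(df)
    )


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test: sum of hypergeometric probabilities of
    all margin-compatible tables no more probable than the observed one.
    Non-2x2 input falls back to Pearson with a warning."""
    if table.shape != (2, 2):
        log.warning("Fisher requested on %sx%s table; using Pearson", *table.shape)
        return chi_square_test(table)
    _check_testable(table)
    _, p = stats.fisher_exact(table.counts, alternative="two-sided")
    return TestResult(method=TestMethod.FISHER_EXACT, p_value=float(p))


def choose_test(table: ContingencyTable) -> TestMethod:
    """Fisher iff the table is 2x2 and any expected cell count is < 5."""
    _check_testable(table)
    small = bool(np.any(table.expected() < 5))
    if small and table.shape == (2, 2):
        return TestMethod.FISHER_EXACT
    if small:
        log.warning("small expected cells in %sx%s table; Pearson used", *table.shape)
    return TestMethod.PEARSON_CHI2


def run_test(table: ContingencyTable) -> TestResult:
    """Select and run the appropriate independence test."""
    if choose_test(table) is TestMethod.FISHER_EXACT:
        return fisher_exact(table)
    return chi_square_test(table)


def collapse_mention(sg_category: MentionCategory | str) -> str:
    """Collapse the three S/G categories to MENTION vs NO_MENTION."""
    cat = MentionCategory(sg_category)
    if cat is MentionCategory.NO_MENTION:
        return "NO_MENTION"
    return "MENTION"


def odds_ratio(table: ContingencyTable) -> OddsRatioResult:
    """Cross-product OR of a 2x2 table [[a, b], [c, d]] with Wald 95% CI.

    The estimate is the odds of the first column in the first row relative
    to the second row; the second row/column are the reference.  A single
    zero cell triggers the Haldane-Anscombe correction (0.5 added to every
    cell, result flagged); a zero row or column margin is undefined.
    """
    if table.shape != (2, 2):
        raise ValueError("odds_ratio requires a 2x2 table")
    a, b, c, d = (float(x) for x in table.counts.ravel())
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise ValueError("odds ratio undefined: a full row or column is zero")
    corrected = False
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    estimate = (a * d) / (b * c)
    log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(estimate)
    return OddsRatioResult(
        estimate=estimate,
        log_se=log_se,
        ci_low=math.exp(log_or - Z_95 * log_se),
        ci_high=math.exp(log_or + Z_95 * log_se),
        reference_row=table.row_labels[1],
        reference_col=table.col_labels[1],
        haldane_corrected=corrected,
    )


def mention_odds_ratio(
    labels_table: pd.DataFrame,
    row_var: str,
    row_level: str,
    reference_level: str,
    filter: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
) -> OddsRatioResult:
    """OR of any S/G mention for one level of a label vs a reference level.

    Builds the 2x2 (row_level, reference_level) x (MENTION, NO_MENTION)
    from the collapsed mention categories.
    """
    df = labels_table
    if filter is not None:
        mask = filter(df) if callable(filter) else filter
        df = df[np.asarray(mask, dtype=bool)]
    df = df.assign(mention=df["sg_category"].map(collapse_mention))
    table = crosstab(
        df,
        row_var,
        "mention",
        row_order=[row_level, reference_level],
        col_order=["MENTION", "NO_MENTION"],
    )
    return odds_ratio(table)


# ---------------------------------------------------------------------------
# report tables

_ORDERS = {
    "sg_category": [c.value for c in MentionCategory],
    "study_type": ["INTERVENTIONAL", "OBSERVATIONAL"],
    "status_group": [
        "ACTIVE_NOT_RECRUITING", "COMPLETED", "NOT_YET_RECRUITING",
        "RECRUITING_OR_INVITATION", "UNKNOWN_OR_SUSPENDED",
    ],
    "enrolment_group": ["LE_100", "GT_100"],
    "hpv_mention": ["True", "False"],
    "subsite_group": ["A_HPV_RELEVANT", "B_OTHER"],
    "phase_group": ["EP1_P1", "P1_P2", "P2_P3", "P4", "NOT_APPLICABLE"],
    "control_class": ["CONTROLLED", "UNCONTROLLED"],
    "randomization": ["RANDOMIZED", "NON_RANDOMIZED"],
}


def variable_order(var: str) -> list[str] | None:
    return _ORDERS.get(var)


def summarize_by_mention(
    labels_table: pd.DataFrame,
    row_vars: Sequence[str],
    col_var: str = "sg_category",
    filter: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
) -> pd.DataFrame:
    """Long-format summary: per variable level, counts and row percentages
    of each column category, with the independence test per variable.

    Realizes the layout of the published characteristics tables; the phase
    block should be computed on interventional studies only by passing a
    filter.
    """
    df = labels_table
    if filter is not None:
        mask = filter(df) if callable(filter) else filter
        df = df[np.asarray(mask, dtype=bool)]
    df = df.astype({col_var: str})
    rows = []
    for var in row_vars:
        table = crosstab(
            df.astype({var: str}),
            var,
            col_var,
            row_order=variable_order(var),
            col_order=variable_order(col_var),
        )
        try:
            result = run_test(table)
            p_value, method = result.p_value, result.method.value
        except ValueError as err:  # single observed level: no test possible
            log.warning("no test for %r: %s", var, err)
            p_value, method = float("nan"), ""
        for i, level in enumerate(table.row_labels):
            row_total = int(table.row_margins[i])
            entry: dict[str, object] = {
                "variable": var,
                "level": level,
                "n": row_total,
                "pct_of_total": 100.0 * row_total / table.total if table.total else np.nan,
                "p_value": p_value,
                "test": method,
            }
            for j, cat in enumerate(table.col_labels):
                count = int(table.counts[i, j])
                entry[f"n_{cat}"] = count
                entry[f"pct_{cat}"] = 100.0 * count / row_total if row_total else np.nan
            rows.append(entry)
    return pd.DataFrame(rows)
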