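"""Yearly submission-count series stratified by study label.

The registry submission year of each study is counted once into its
stratum (S/G mention category or HPV mention), producing a contiguous
yearly series; intermediate years with no submissions appear with zero
counts.  Two years' stratum shares are compared with Fisher's exact test
on the 2x2 (stratum / other) x (year1 / year2) table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association_stats import ContingencyTable, TestResult, fisher_exact


@dataclass
class TrendSeries:
    """Per-year counts per stratum over a contiguous year range."""

    years: list[int]
    counts: pd.DataFrame  # index: years, columns: stratum labels

    def year_total(self, year: int) -> int:
        if year not in self.counts.index:
            raise KeyError(f"year {year} not in series")
        return int(self.counts.loc[year].sum())

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def yearly_series(
    labels_table: pd.DataFrame,
    stratum_var: str,
    year_var: str = "submission_year",
    snapshot_year: int | None = None,
) -> TrendSeries:
    """Count every study once into its submission year and stratum.

    Years are made contiguous over [first observed, last observed] (or the
    snapshot year when given); a study dated after the snapshot year is an
    error.  An empty table yields an empty series.
    """
    if stratum_var not in labels_table.columns:
        raise KeyError(f"unknown variable {stratum_var!r}")
    df = labels_table
    if df.empty:
        return TrendSeries(years=[], counts=pd.DataFrame())
    if df[year_var].isna().any():
        missing = df.loc[df[year_var].isna(), "nct_id"].tolist()
        raise ValueError(f"submission year missing for {missing}")
    years = df[year_var].astype(int)
    last = int(years.max())
    if snapshot_year is not None:
        if last > snapshot_year:
            bad = df.loc[years > snapshot_year, "nct_id"].tolist()
            raise ValueError(f"studies dated after the snapshot year: {bad}")
        last = snapshot_year
    full = list(range(int(years.min()), last + 1))
    frame = (
        pd.crosstab(years, df[stratum_var].astype(str))
        .reindex(full, fill_value=0)
        .sort_index(axis=1)
    )
    return TrendSeries(years=full, counts=frame)


def compare_year_proportions(
    series: TrendSeries, stratum: str, year1: int, year2: int
) -> TestResult:
    """Fisher exact test of the stratum share in year1 vs year2."""
    for year in (year1, year2):
        if year not in series.counts.index:
            raise KeyError(f"year {year} not in series")
        if series.year_total(year) == 0:
            raise ValueError(f"year {year} has no submissions")
    if stratum not in series.counts.columns:
        raise KeyError(f"stratum {stratum!r} not in series")
    k1 = int(series.counts.loc[year1, stratum])
    k2 = int(series.counts.loc[year2, stratum])
    n1, n2 = series.year_total(year1), series.year_total(year2)
    from .association_stats import TestMethod

    if (k1 == 0 and k2 == 0) or (k1 == n1 and k2 == n2):
        # the stratum (or its complement) is empty in both years: no evidence
        return TestResult(method=TestMethod.FISHER_EXACT, p_value=1.0)
    table = ContingencyTable(
        row_labels=[str(year1), str(year2)],
        col_labels=[stratum, "OTHER"],
        counts=np.array([[k1, n1 - k1], [k2, n2 - k2]]),
    )
    return fisher_exact(table)
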