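"""Odds ratios with Wald confidence intervals from reference table cells.

The reference module ships the published cross-tabulation counts of the
1672-study head-and-neck-cancer cohort; the mention-collapsed 2x2 analyses
recompute from those cells.
"""

from hncmeta import chi_square_test, odds_ratio
from hncmeta.reference import (
    MENTION_BY_ENROLMENT,
    MENTION_BY_PHASE,
    MENTION_BY_STUDY_TYPE,
    STUDY_TYPE_BY_CATEGORY,
)

for name, table in [
    ("interventional vs observational", MENTION_BY_STUDY_TYPE),
    ("<=100 vs >100 subjects         ", MENTION_BY_ENROLMENT),
    ("phase 2/3 vs early phase 1/1   ", MENTION_BY_PHASE),
]:
    r = odds_ratio(table)
    print(f"S/G mention, {name}: OR {r.estimate:.2f} "
          f"[{r.ci_low:.2f}-{r.ci_high:.2f}] (ref: {r.reference_row})")
# Expected: 5.76 [4.29-7.72], 1.29 [1.04-1.60], 0.63 [0.42-0.94] — an OR
# above 1 means the first-listed group mentions sex/gender more often.

t = chi_square_test(STUDY_TYPE_BY_CATEGORY)
print(f"\nstudy type x S/G category: chi2={t.statistic:.1f}, "
      f"df={t.df}, p={t.p_value:.2e}")
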