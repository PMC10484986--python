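"""Reference cross-tabulation counts for head-and-neck-cancer registrations.

These are published summary counts from a cross-sectional analysis of the
1672 head-and-neck-cancer studies registered on ClinicalTrials.gov and open
to all sexes (AACT snapshot of 12 April 2022), cross-tabulated by sex/gender
(S/G) mention category.  They serve as fixed *inputs* for recomputing the
reported association statistics: each 2x2 below collapses the S/G
categories to "some mention" vs "no mention" for two levels of one study
characteristic, laid out as

    [[mention_level1, no_mention_level1],
     [mention_level2, no_mention_level2]]

with the second row as the reference level.
"""

from __future__ import annotations

import numpy as np

from .association_stats import ContingencyTable

#: full S/G-category cross-tabulation by study type
#: rows: interventional, observational; cols: analytical, recruitment-only, none
STUDY_TYPE_BY_CATEGORY = ContingencyTable(
    row_labels=["INTERVENTIONAL", "OBSERVATIONAL"],
    col_labels=["ANALYTICAL", "RECRUITMENT_ONLY", "NO_MENTION"],
    counts=np.array([[63, 897, 447], [26, 46, 193]]),
)

#: mention-collapsed 2x2: interventional vs observational (reference)
MENTION_BY_STUDY_TYPE = ContingencyTable(
    row_labels=["INTERVENTIONAL", "OBSERVATIONAL"],
    col_labels=["MENTION", "NO_MENTION"],
    counts=np.array([[960, 447], [72, 193]]),
)

#: mention-collapsed 2x2: enrolment <=100 (incl. missing) vs >100 (reference)
MENTION_BY_ENROLMENT = ContingencyTable(
    row_labels=["LE_100", "GT_100"],
    col_labels=["MENTION", "NO_MENTION"],
    counts=np.array([[750, 431], [282, 209]]),
)

#: mention-collapsed 2x2: phase 2/3 vs early phase 1 / phase 1 (reference)
MENTION_BY_PHASE = ContingencyTable(
    row_labels=["P2_P3", "EP1_P1"],
    col_labels=["MENTION", "NO_MENTION"],
    counts=np.array([[606, 214], [149, 33]]),
)

#: HPV-relevant-subsite (group A) stratum: HPV mention vs status,
#: Completed vs Active-not-recruiting (reference)
SUBSITE_A_HPV_BY_STATUS_COMPLETED = ContingencyTable(
    row_labels=["COMPLETED", "ACTIVE_NOT_RECRUITING"],
    col_labels=["HPV_MENTION", "HPV_NO_MENTION"],
    counts=np.array([[23, 164], [20, 36]]),
)
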