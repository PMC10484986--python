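"""Rule-based selection of the head-and-neck-cancer (HNC) analysis cohort.

A condition name is a *neoplasm* condition when it contains one of six
case-insensitive substrings ("neopl", "cancer", "malignan", "tumor",
"carcino", "onco"), and an *HNC* condition when it is a neoplasm condition
that also names a head-and-neck region ("head", "neck", "larynx", ...).
Matching is plain substring matching with no word boundaries: the published
term lists are deliberate stems.  Note the region list carries "larynx"
and "pharynx" in full, so e.g. "laryngeal cancer" does *not* qualify on its
own — in practice the MeSH browse conditions ("Laryngeal Neoplasms" plus
"Head and Neck Neoplasms" etc.) carry such studies into the cohort.

The HNC-condition index of a study is the fraction of its listed conditions
that are HNC conditions; a study enters the cohort only when HNC is its
unique investigated topic (index 1.0 in the free-text conditions or in the
MeSH terms), it is not Withdrawn/Terminated, and it is open to all sexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .lexicons import Lexicon, neoplasm_lexicon, region_lexicon
from .registry_io import EligibilitySex, RegistryBundle, StudyRecord

log = logging.getLogger(__name__)

#: statuses removed from the cohort
EXCLUDED_STATUSES = frozenset({"withdrawn", "terminated"})


@dataclass
class CohortReport:
    """Per-gate accounting of the hierarchical cohort selection."""

    n_screened: int
    n_hnc_unique: int
    n_excluded_status: int
    n_excluded_single_sex: int
    included_ids: list[str] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return len(self.included_ids)

    def to_dict(self) -> dict[str, object]:
        return {
            "n_screened": self.n_screened,
            "n_hnc_unique": self.n_hnc_unique,
            "n_excluded_status": self.n_excluded_status,
            "n_excluded_single_sex": self.n_excluded_single_sex,
            "n_included": self.n_included,
            "included_ids": list(self.included_ids),
        }


def _contains_any(name: str, lexicon: Lexicon) -> bool:
    low = name.lower()
    return any(term in low for term in lexicon.terms)


def is_neoplasm_condition(condition_name: str) -> bool:
    """True iff the name contains one of the six neoplasm substrings."""
    return _contains_any(condition_name, neoplasm_lexicon())


def is_hnc_condition(condition_name: str) -> bool:
    """True iff the name is a neoplasm condition naming a head-neck region."""
    return is_neoplasm_condition(condition_name) and _contains_any(
        condition_name, region_lexicon()
    )


def hnc_condition_index(conditions: list[str]) -> float:
    """Fraction of the study's conditions that are HNC conditions.

    Raises ``ValueError`` for an empty list (the index is undefined);
    callers treat such studies as non-HNC.
    """
    if not conditions:
        raise ValueError("hnc_condition_index is undefined for an empty condition list")
    return sum(is_hnc_condition(c) for c in conditions) / len(conditions)


def _source_index(conditions: list[str]) -> float | None:
    if not conditions:
        return None
    return hnc_condition_index(conditions)


def is_hnc_unique(record: StudyRecord) -> bool:
    """True when HNC is the study's unique topic in either condition source.

    The free-text ``conditions`` table and the MeSH ``browse_conditions``
    terms are screened independently; an index of exactly 1.0 in either
    source qualifies.  A study with both sources empty is non-HNC.
    """
    free = _source_index(record.conditions)
    mesh = _source_index(record.mesh_terms)
    if free is None and mesh is None:
        log.warning("%s: no conditions listed; treated as non-HNC", record.nct_id)
        return False
    return free == 1.0 or mesh == 1.0


def gate_table(bundle: RegistryBundle) -> pd.DataFrame:
    """Per-study gate outcomes: HNC uniqueness, status gate, sex gate."""
    rows = []
    for rec in bundle:
        hnc = is_hnc_unique(rec)
        status_ok = rec.overall_status.strip().lower() not in EXCLUDED_STATUSES
        sex_ok = rec.eligibility_sex == EligibilitySex.ALL
        rows.append(
            {
                "nct_id": rec.nct_id,
                "hnc_unique": hnc,
                "status_ok": status_ok,
                "sex_ok": sex_ok,
                "included": hnc and status_ok and sex_ok,
            }
        )
    return pd.DataFrame(
        rows, columns=["nct_id", "hnc_unique", "status_ok", "sex_ok", "included"]
    )


def select_cohort(bundle: RegistryBundle) -> CohortReport:
    """Apply the three exclusion gates in order and account per gate.

    Order: (1) HNC as unique condition; (2) status not Withdrawn/Terminated;
    (3) eligibility open to all sexes.  Each excluded study is counted at
    the first gate it fails, so the counts satisfy
    ``n_hnc_unique == n_excluded_status + n_excluded_single_sex + n_included``.
    """
    gates = gate_table(bundle)
    hnc = gates[gates["hnc_unique"]]
    excluded_status = hnc[~hnc["status_ok"]]
    remaining = hnc[hnc["status_ok"]]
    excluded_sex = remaining[~remaining["sex_ok"]]
    included = remaining[remaining["sex_ok"]]
    return CohortReport(
        n_screened=len(gates),
        n_hnc_unique=len(hnc),
        n_excluded_status=len(excluded_status),
        n_excluded_single_sex=len(excluded_sex),
        included_ids=included["nct_id"].tolist(),
    )
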