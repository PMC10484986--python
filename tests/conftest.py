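"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re
from datetime import date
from math import comb

import pytest

from hncmeta import EligibilitySex, RegistryBundle, StudyRecord


def make_record(nct_id: str = "NCT00000001", **kwargs) -> StudyRecord:
    """A minimal well-formed cohort-eligible study record."""
    defaults = dict(
        brief_title="Evaluation of cisplatin for cancer of the larynx",
        conditions=["cancer of the larynx"],
        mesh_terms=["Head and Neck Neoplasms"],
        eligibility_sex=EligibilitySex.ALL,
        overall_status="Completed",
        study_type="Interventional",
        phase_raw="Phase 2",
        enrollment=40,
        first_submitted=date(2015, 6, 1),
    )
    defaults.update(kwargs)
    return StudyRecord(nct_id=nct_id, **defaults)


def make_bundle(*records: StudyRecord) -> RegistryBundle:
    return RegistryBundle(studies={r.nct_id: r for r in records})


@pytest.fixture
def record() -> StudyRecord:
    return make_record()


# ---------------------------------------------------------------------------
# independent oracles


def scan_match(text: str, term: str, mode: str) -> bool:
    """Character-scanning term matcher, independent of the regex path.

    Lower-cases, collapses whitespace runs, then scans every start offset.
    ``mode`` is "word", "stem" or "substring"; word boundaries are
    non-alphabetic characters or the text edges.
    """
    text = re.sub(r"\s+", " ", text).lower()
    n, m = len(text), len(term)
    for i in range(n - m + 1):
        if text[i : i + m] != term:
            continue
        if mode == "substring":
            return True
        before_ok = i == 0 or not ("a" <= text[i - 1] <= "z")
        after_ok = i + m == n or not ("a" <= text[i + m] <= "z")
        if mode == "stem" and before_ok:
            return True
        if mode == "word" and before_ok and after_ok:
            return True
    return False


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of margin-compatible tables."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def pearson_2x2_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Classical 2x2 chi-square statistic n(ad-bc)^2 / product of margins."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
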