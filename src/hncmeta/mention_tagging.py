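"""Detection of sex/gender (S/G) and HPV terms in registration text.

Every study receives exactly one S/G mention category:

``ANALYTICAL``
    an S/G term occurs in at least one ANALYSIS section (titles, summaries,
    detailed description, outcome measures, arm-group titles, intervention
    descriptions) — S/G is treated as a planned analytical variable;
``RECRUITMENT_ONLY``
    S/G terms occur only in the eligibility population/criteria text;
``NO_MENTION``
    no S/G term anywhere.

The hierarchy is strict: an analysis-section hit dominates any eligibility
hit.  The structured eligible-sex field ("All") is *not* itself a mention —
only free-text term hits count.  Matching is case-insensitive; whole-word
boundaries are any non-letter character or the text edge (hyphens and
digits are boundaries), so "men" matches in "women and men" but not inside
"treatment" or "women", while the stems "pregnan"/"transg" match any word
they begin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .lexicons import Lexicon, MatchMode, hpv_lexicon, sg_lexicon, subsite_lexicon
from .registry_io import (
    ANALYSIS_SECTIONS,
    ELIGIBILITY_SECTIONS,
    RegistryBundle,
    StudyRecord,
    section_map,
)


class MentionCategory(str, Enum):
    ANALYTICAL = "ANALYTICAL"
    RECRUITMENT_ONLY = "RECRUITMENT_ONLY"
    NO_MENTION = "NO_MENTION"


class SubsiteGroup(str, Enum):
    A_HPV_RELEVANT = "A_HPV_RELEVANT"
    B_OTHER = "B_OTHER"


@dataclass
class TagResult:
    """All mention-level labels of one study, with the supporting hits."""

    nct_id: str
    sg_category: MentionCategory
    sg_hits: list[tuple[str, str]] = field(default_factory=list)  # (section, term)
    hpv_mention: bool = False
    hpv_hits: list[tuple[str, str]] = field(default_factory=list)
    subsite_group: SubsiteGroup = SubsiteGroup.B_OTHER


_WS_RUN = re.compile(r"\s+")


def _normalize(text: str) -> str:
    return _WS_RUN.sub(" ", text).lower()


def _entry_pattern(term: str, mode: MatchMode) -> re.Pattern[str] | None:
    escaped = re.escape(term)
    if mode is MatchMode.WHOLE_WORD:
        return re.compile(rf"(?<![a-z]){escaped}(?![a-z])")
    if mode is MatchMode.PREFIX_STEM:
        return re.compile(rf"(?<![a-z]){escaped}")
    return None  # SUBSTRING handled by `in`


def match_terms(text: str, lexicon: Lexicon) -> list[str]:
    """Return the lexicon terms matching ``text``, each at most once.

    Results preserve lexicon order; whitespace runs are collapsed before
    matching so multi-word substring entries match across line breaks.
    """
    low = _normalize(text)
    hits: list[str] = []
    for term, mode in lexicon.entries:
        pattern = _entry_pattern(term, mode)
        found = term in low if pattern is None else bool(pattern.search(low))
        if found:
            hits.append(term)
    return hits


def section_hits(
    sections: dict[str, str], lexicon: Lexicon
) -> list[tuple[str, str]]:
    """All ``(section_id, term)`` pairs for a section map."""
    out: list[tuple[str, str]] = []
    for sid, text in sections.items():
        for term in match_terms(text, lexicon):
            out.append((sid, term))
    return out


def classify_sg(
    sections: dict[str, str], lexicon: Lexicon | None = None
) -> MentionCategory:
    """Assign the S/G mention category of one study from its section map."""
    lexicon = lexicon or sg_lexicon()
    hits = section_hits(sections, lexicon)
    sections_hit = {sid for sid, _ in hits}
    if sections_hit & set(ANALYSIS_SECTIONS):
        return MentionCategory.ANALYTICAL
    if sections_hit & set(ELIGIBILITY_SECTIONS):
        return MentionCategory.RECRUITMENT_ONLY
    return MentionCategory.NO_MENTION


def detect_hpv(record: StudyRecord, lexicon: Lexicon | None = None) -> bool:
    """True iff any HPV string matches in any targeted field.

    The search covers all targeted free-text sections plus the condition
    names (free-text and MeSH).
    """
    lexicon = lexicon or hpv_lexicon()
    fields = dict(section_map(record))
    fields["conditions"] = "\n".join(record.all_conditions())
    return bool(section_hits(fields, lexicon))


def assign_subsite_group(
    conditions: list[str], lexicon: Lexicon | None = None
) -> SubsiteGroup:
    """Group A iff any condition names an HPV-relevant subsite.

    The subsite strings ("oral cavity", "pharyn", "laryn", "tonsil",
    "base of tongue") match as plain case-insensitive substrings.
    """
    lexicon = lexicon or subsite_lexicon()
    for name in conditions:
        low = _normalize(name)
        if any(term in low for term in lexicon.terms):
            return SubsiteGroup.A_HPV_RELEVANT
    return SubsiteGroup.B_OTHER


def tag_study(
    record: StudyRecord,
    sg_lex: Lexicon | None = None,
    hpv_lex: Lexicon | None = None,
    subsite_lex: Lexicon | None = None,
) -> TagResult:
    """Compute all mention-level labels of one study."""
    sg_lex = sg_lex or sg_lexicon()
    hpv_lex = hpv_lex or hpv_lexicon()
    sections = section_map(record)
    sg_hit_list = section_hits(sections, sg_lex)
    category = classify_sg(sections, sg_lex)

    fields = dict(sections)
    fields["conditions"] = "\n".join(record.all_conditions())
    hpv_hit_list = section_hits(fields, hpv_lex)
    return TagResult(
        nct_id=record.nct_id,
        sg_category=category,
        sg_hits=sg_hit_list,
        hpv_mention=bool(hpv_hit_list),
        hpv_hits=hpv_hit_list,
        subsite_group=assign_subsite_group(record.all_conditions(), subsite_lex),
    )


def tag_cohort(
    bundle: RegistryBundle,
    included_ids: list[str] | None = None,
    sg_lex: Lexicon | None = None,
    hpv_lex: Lexicon | None = None,
    subsite_lex: Lexicon | None = None,
) -> pd.DataFrame:
    """Tag every (included) study; one row per study."""
    ids = list(included_ids) if included_ids is not None else list(bundle.studies)
    rows = []
    for nct_id in ids:
        tag = tag_study(bundle[nct_id], sg_lex, hpv_lex, subsite_lex)
        rows.append(
            {
                "nct_id": tag.nct_id,
                "sg_category": tag.sg_category.value,
                "hpv_mention": tag.hpv_mention,
                "subsite_group": tag.subsite_group.value,
                "sg_hits": ";".join(f"{s}:{t}" for s, t in tag.sg_hits),
                "hpv_hits": ";".join(f"{s}:{t}" for s, t in tag.hpv_hits),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["nct_id", "sg_category", "hpv_mention", "subsite_group", "sg_hits", "hpv_hits"],
    )
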