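"""Term matching semantics and the hierarchical mention classifier."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hncmeta import (
    ANALYSIS_SECTIONS,
    MentionCategory,
    SubsiteGroup,
    assign_subsite_group,
    classify_sg,
    detect_hpv,
    match_terms,
    section_map,
    tag_study,
)
from hncmeta.lexicons import Lexicon, MatchMode, hpv_lexicon, sg_lexicon

from conftest import make_record, scan_match


def test_whole_word_boundaries():
    hits = match_terms("women and men were enrolled", sg_lexicon())
    assert "women" in hits and "men" in hits
    assert "man" not in hits and "woman" not in hits


def test_embedded_substrings_do_not_match():
    assert match_terms("human papillomavirus treatment", sg_lexicon()) == []
    assert match_terms("disease management regimen", sg_lexicon()) == []


def test_prefix_stem_matches_word_beginnings():
    assert match_terms("pregnant or breastfeeding subjects are excluded",
                       sg_lexicon()) == ["pregnan"]
    assert "transg" in match_terms("transgender participants welcome", sg_lexicon())
    # stems do not fire mid-word
    assert match_terms("nonpregnant subjects", sg_lexicon()) == []


def test_hyphen_and_digit_are_word_boundaries():
    assert "male" in match_terms("male-specific outcomes", sg_lexicon())
    assert "sex" in match_terms("sex2 subgroup", sg_lexicon())


def test_each_entry_reported_at_most_once():
    assert match_terms("men and men and men", sg_lexicon()).count("men") == 1


# boundary-trap vocabulary: words that embed S/G terms without containing
# them as whole words, plus genuine term words
TRAPS = ["women", "management", "semen", "human", "treatment", "acumen",
         "man", "men", "male", "females", "sex", "unisex", "gendered",
         "pregnant", "transgender", "boy", "boys", "girls", "regimen"]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(TRAPS), min_size=0, max_size=12))
def test_match_terms_agrees_with_character_scan_oracle(words):
    sentence = " ".join(words)
    lexicon = sg_lexicon()
    hits = set(match_terms(sentence, lexicon))
    expected = {
        term
        for term, mode in lexicon.entries
        if scan_match(sentence, term, mode.value)
    }
    assert hits == expected


def test_classify_sg_hierarchy():
    base = {s: "" for s in section_map(make_record())}
    analytical = dict(base, outcomes="response stratified by sex")
    assert classify_sg(analytical) is MentionCategory.ANALYTICAL
    recruitment = dict(base, eligibility_criteria="pregnant participants excluded")
    assert classify_sg(recruitment) is MentionCategory.RECRUITMENT_ONLY
    assert classify_sg(base) is MentionCategory.NO_MENTION
    # an analysis hit dominates any eligibility hit
    both = dict(analytical, eligibility_criteria="women excluded")
    assert classify_sg(both) is MentionCategory.ANALYTICAL


@pytest.mark.parametrize("section", ANALYSIS_SECTIONS)
def test_any_analysis_section_hit_is_analytical(section):
    sections = {s: "" for s in section_map(make_record())}
    sections[section] = "subgroup analysis by gender"
    assert classify_sg(sections) is MentionCategory.ANALYTICAL


def test_adding_analysis_term_flips_recruitment_to_analytical():
    rec = make_record(eligibility_criteria="pregnant participants are excluded")
    assert tag_study(rec).sg_category is MentionCategory.RECRUITMENT_ONLY
    upgraded = make_record(
        eligibility_criteria="pregnant participants are excluded",
        detailed_description="Results will be stratified by sex.",
    )
    assert tag_study(upgraded).sg_category is MentionCategory.ANALYTICAL
    # removing the eligibility text never demotes an analytical study
    stripped = make_record(detailed_description="Results will be stratified by sex.")
    assert tag_study(stripped).sg_category is MentionCategory.ANALYTICAL


def test_structured_sex_field_is_not_a_mention():
    rec = make_record()  # eligibility_sex=ALL, no free-text term anywhere
    assert tag_study(rec).sg_category is MentionCategory.NO_MENTION


def test_detect_hpv_in_condition_and_text():
    assert detect_hpv(
        make_record(conditions=["HPV-Positive Oropharyngeal Squamous Cell Carcinoma"])
    )
    assert detect_hpv(
        make_record(brief_summary="papillomavirus, human vaccination history")
    )
    assert detect_hpv(make_record(detailed_description="HPV16 status is recorded"))
    assert not detect_hpv(make_record())


def test_hpv_term_does_not_trigger_sg():
    rec = make_record(brief_summary="human papillomavirus status will be recorded")
    tag = tag_study(rec)
    assert tag.hpv_mention and tag.sg_category is MentionCategory.NO_MENTION


@pytest.mark.parametrize(
    ("condition", "expected"),
    [
        ("oropharyngeal carcinoma", SubsiteGroup.A_HPV_RELEVANT),
        ("carcinoma of the base of tongue", SubsiteGroup.A_HPV_RELEVANT),
        ("laryngeal cancer", SubsiteGroup.A_HPV_RELEVANT),  # "laryn" stem
        ("tonsillar hypertrophy", SubsiteGroup.A_HPV_RELEVANT),
        ("paranasal sinus cancer", SubsiteGroup.B_OTHER),
        ("head and neck neoplasms", SubsiteGroup.B_OTHER),
    ],
)
def test_assign_subsite_group(condition, expected):
    assert assign_subsite_group([condition]) is expected


def test_custom_lexicon_modes():
    lex = Lexicon(
        "toy",
        (("abc", MatchMode.WHOLE_WORD), ("xy", MatchMode.PREFIX_STEM),
         ("zz", MatchMode.SUBSTRING)),
    )
    assert match_terms("abc xylophone buzzing", lex) == ["abc", "xy", "zz"]
    assert match_terms("abcd", lex) == []


def test_lexicon_validation():
    with pytest.raises(ValueError):
        Lexicon("empty", ())
    with pytest.raises(ValueError):
        Lexicon("dupe", (("a", MatchMode.WHOLE_WORD), ("a", MatchMode.WHOLE_WORD)))
    with pytest.raises(ValueError):
        Lexicon("case", (("Sex", MatchMode.WHOLE_WORD),))
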