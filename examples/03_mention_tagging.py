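"""Term matching semantics and the hierarchical S/G mention classifier."""

from hncmeta import StudyRecord, match_terms, sg_lexicon, tag_study

lex = sg_lexicon()
for sentence in [
    "women and men were enrolled",          # whole words match
    "human papillomavirus treatment",        # embedded "man"/"men" do not
    "pregnant participants are excluded",    # the stem "pregnan" matches
]:
    print(f"{sentence!r:45s} -> {match_terms(sentence, lex)}")

analytical = StudyRecord(
    nct_id="NCT00000001",
    detailed_description="Survival will be stratified by sex.",
    eligibility_criteria="Pregnant participants are excluded.",
)
recruitment = StudyRecord(
    nct_id="NCT00000002",
    eligibility_criteria="Pregnant participants are excluded.",
)
for rec in (analytical, recruitment):
    tag = tag_study(rec)
    print(rec.nct_id, "->", tag.sg_category.value, "| hits:", tag.sg_hits)
# The hierarchy is strict: one hit in an analysis-oriented section makes a
# study ANALYTICAL even when eligibility text also mentions a term.
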