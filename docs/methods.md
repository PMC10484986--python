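# Methods

## Scope and data model

`hncmeta` audits sex/gender (S/G) and HPV consideration in head-and-neck-
cancer (HNC) study registrations.  Its input is an AACT-style relational
export of ClinicalTrials.gov: per-table delimited text files (`studies`,
`conditions`, `browse_conditions`, `eligibilities`, `designs`,
`design_groups`, `design_outcomes`, `interventions`, `brief_summaries`,
`detailed_descriptions`) keyed by NCT id, with the column names of the
public AACT data dictionary.  `registry_io.load_registry` joins these into
one `StudyRecord` per study; absent auxiliary tables yield empty fields,
duplicate NCT ids are fatal.  Text is treated as UTF-8 and preserved as-is
(en-dashes, typographic quotes).  A record with no eligibility sex value is
treated as open to all sexes with a warning, because exclusion keys on an
explicit Male/Female selection.

The targeted free-text sections are fixed and total
(`registry_io.section_map`): ANALYSIS sections = brief/official title,
brief summary, detailed description, outcome measures+descriptions,
arm-group *titles* (group descriptions are not searched), intervention
descriptions; ELIGIBILITY sections = eligibility population and criteria.
List-valued sections concatenate with newlines so whole-word matches cannot
span entries.

## Cohort selection

Condition matching is case-insensitive plain-substring over two published
stem lists (neoplasm stems and head-neck region strings); no word
boundaries are applied because the lists are deliberate stems ("neopl",
"otorinolar").  A consequence worth knowing: the region list carries
"larynx"/"pharynx" in full, so adjectival forms ("laryngeal cancer") do
not match by themselves — in real exports the MeSH browse conditions
("Laryngeal Neoplasms", "Head and Neck Neoplasms") carry such studies.
Both condition sources are therefore screened and a study qualifies when
*either* source has an HNC-condition index of exactly 1.0 (HNC as the
unique investigated topic).  Studies with no conditions at all fail this
gate.  The remaining gates run hierarchically — status not
Withdrawn/Terminated, then eligibility open to all sexes — and each
exclusion is counted at the first gate it fails, giving the accounting
identity `n_hnc_unique = n_excluded_status + n_excluded_single_sex +
n_included`.

## Mention tagging

Three match modes: whole-word (boundary = any non-letter character or text
edge; hyphens and digits are boundaries), prefix-stem (word must *begin*
with the stem), and substring (after collapsing whitespace runs, so
multi-word entries match across line breaks).  All S/G terms are whole
words except the stems `pregnan` and `transg`; substring matching of
"man"/"men"/"male" would fire inside "human", "treatment", "females" and
make the category counts meaningless.  The structured eligible-sex field
("All") is never itself a mention.

The category assignment is strictly hierarchical: any analysis-section hit
→ ANALYTICAL; else any eligibility hit → RECRUITMENT_ONLY; else
NO_MENTION.  The three categories partition every cohort.

HPV strings are MeSH-derived; multi-word entries match as substrings,
bare `hpv` is listed both as a whole word and as a substring so that
"HPV16" and "HPV-positive" match regardless of boundary conventions.  The
HPV search covers all targeted sections plus both condition sources.
Subsite group A (HPV-relevant: oral cavity / pharynx / larynx / tonsil /
base of tongue) is assigned from condition names by plain substring; the
stem "pharyn" intentionally also captures naso-/hypopharynx.

## Design labels

- Controlled iff any arm type is exactly (case-insensitively) one of
  Experimental, Active Comparator, Placebo Comparator, Sham Comparator;
  unknown arm types are non-qualifying with a warning; no arms =
  uncontrolled.
- Randomized iff the allocation field reads "Randomized"; absent or other
  values (including observational studies, which have no allocation) are
  non-randomized.
- Phase groups: {Early Phase 1, Phase 1} → EP1/P1; {Phase 1/Phase 2} →
  P1/P2; {Phase 2, Phase 2/Phase 3, Phase 3} → P2/P3; {Phase 4} → P4;
  missing/N-A/unknown → Not Applicable.  Phase 2 and Phase 3 pool into
  P2/P3 so the five groups exhaust all interventional studies.
  Observational studies are always Not Applicable.
- Enrolment dichotomizes at 100 subjects; missing pools with ≤100.  The
  single `enrollment` column of the studies table is used as-is (AACT's
  actual-vs-anticipated distinction collapses to whichever value the
  export carries).
- Status groups merge Recruiting with Enrolling-by-invitation and Unknown
  with Suspended; unrecognized statuses pool with Unknown/Suspended.
- Submission year comes from the first-submitted date; trend series reject
  studies dated after the snapshot year.

## Statistics

Tests run through scipy (`chi2_contingency` without continuity correction;
`fisher_exact`, two-sided by the "sum of no-more-probable tables" rule).
The selection rule — Fisher iff the table is 2×2 and any expected count is
below 5, Pearson otherwise (with a warning for small non-2×2 tables) — is
the standard convention; every report records which test ran.  The test
suite cross-checks both against independent oracles: an exhaustive
hypergeometric enumeration (all 2×2 tables with margins ≤ 12, built from
binomial coefficients only) and the classical closed form
`n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`.

Odds ratios are plain cross-products with a Wald 95% CI on the log scale
(z = 1.96); a single zero cell triggers the Haldane–Anscombe +0.5
correction and flags the result; a zero row/column margin is an error.
Every result carries its reference orientation (second row/column).  This
estimator reproduces the reference cohort's printed values 5.76
[4.29–7.72] (interventional vs observational), 1.29 [1.04–1.60] (≤100 vs
>100 subjects) and 0.63 [0.42–0.94] (phase 2/3 vs early phase 1/phase 1)
exactly at 2-decimal rounding from the shipped table cells.  A few
subsite-stratified reference odds ratios (e.g. 0.17 for group-B Completed,
0.52 for the A-vs-B enrolment contrast) do not equal the plain
cross-product of their printed cells at 2 decimals; the estimator behind
those published numbers is unclear, so the cross-product is kept and only
the cleanly recomputable values are asserted.

No multivariable adjustment or multiplicity correction is applied: the
analysis is deliberately univariable.

## Synthetic registry

The generator plants every label a study will later be assigned:
conditions are built from neoplasm+region templates (with controllable
fully-HNC / mixed / non-HNC fractions), S/G terms are injected per section
with configurable probabilities, HPV strings and subsite-A conditions with
their own rates, and design fields are sampled from explicit vocabularies.
One integer seed drives everything; per-study substreams derive from
(seed, index) so draws are independent of generation order.

Defaults emulate the reference cohort's composition: 84% interventional
(86% of those controlled, 38% randomized), S/G section probabilities tuned
to ≈5% analytical / ≈57% recruitment-only / ≈38% no mention, 17% HPV
mention, 34% subsite A, lognormal enrolment (log-mean 3.87, log-sd 1.4,
≈70% at ≤100 subjects, 2% missing), submissions rising linearly over
1999–2022, 14% withdrawn/terminated, 0.4% single-sex, 12% failing the
HNC-uniqueness gate.  Decoy words ("human", "treatment", "management", …)
embed S/G substrings without whole-word occurrences at a configurable rate;
template sentences otherwise avoid all lexicon vocabulary.

What passing tests show — and do not show: with non-overlapping vocabulary
the pipeline recovers every planted label exactly (and a deliberately
substring-matched lexicon does not, which regression-tests the boundary
rule).  This validates the *rules as implemented*, not their linguistic
adequacy on free-text registry prose, where negations, abbreviations and
unanticipated word forms occur.  The generator makes no attempt at
linguistic realism; template sentences suffice for rule-based matching.

## Problem sizes and numerics

The acceptance script uses a 5000-study registry for recovery (a few
seconds on one CPU), the full margin-≤12 Fisher sweep (5238 tables), and
500 random tables for the Pearson closed form.  Reported values round to
2 decimals (ORs/CIs) or 1 decimal (percentages), matching the reference
reporting style.  Tolerances in tests are machine-precision for algebraic
identities and oracle agreements, and exact at printed precision for the
reference recomputations.

## Known limitations

- The absolute reference counts (1952 screened / 1672 included) are not
  reproducible without the specific April-2022 registry snapshot; the
  package reproduces the *rules* and the statistics recomputable from the
  published cells.
- Substring condition rules over- and under-match in known ways (see the
  "laryngeal cancer" note); no guard is added beyond what the published
  string lists imply.
- No natural-language understanding: mentions are counted without negation
  handling and without distinguishing sex from gender.
- r×c Fisher tests beyond 2×2 are not implemented; Pearson is used with a
  warning.
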