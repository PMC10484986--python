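"""Seeded generator of AACT-shaped registries with planted ground truth.

Every pipeline stage is testable without a registry download: the generator
emits the same delimited tables :mod:`hncmeta.registry_io` reads, together
with the planted per-study truth labels (S/G category, HPV flag, subsite
group, design labels and the cohort-gate outcomes).

Free-text sections are template sentences with insertion slots.  The
template vocabulary contains no sex/gender or HPV lexicon word, so the only
matches a correctly configured tagger can find are the planted ones;
optional decoy words ("human", "treatment", "management", ...) embed
lexicon substrings without whole-word occurrences and exercise the word
boundary rule.  The default parameters emulate the composition of the
published 2022 head-and-neck-cancer cohort (84% interventional, ~5%
analytical S/G mention, ~17% HPV mention, ~34% HPV-relevant subsites, 70%
of studies at or below 100 subjects, submissions rising over 1999-2022),
plus small planted fractions of non-HNC, withdrawn/terminated and
single-sex studies so every exclusion gate fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .registry_io import (
    ANALYSIS_SECTIONS,
    ELIGIBILITY_SECTIONS,
    EligibilitySex,
    RegistryBundle,
    StudyRecord,
    write_registry,
)

# HNC condition templates; group A names an HPV-relevant subsite, group B
# does not, and both satisfy the neoplasm + head-neck-region string rules.
CONDITIONS_SUBSITE_A = (
    "cancer of the larynx",
    "oral cavity cancer",
    "tonsil carcinoma",
    "carcinoma of the pharynx",
    "cancer of the base of tongue",
)
CONDITIONS_SUBSITE_B = (
    "head and neck neoplasms",
    "paranasal sinus carcinoma",
    "salivary gland tumor",
    "mouth neoplasm",
    "neck malignancy",
)
CONDITIONS_NON_HNC = (
    "hypertension",
    "type 2 diabetes",
    "breast cancer",
    "chronic kidney disease",
    "asthma",
)

DRUGS = ("cisplatin", "docetaxel", "nivolumab", "radiotherapy", "ABT-101")

#: boundary traps: embed S/G substrings without whole-word occurrences
DECOY_WORDS = ("human", "treatment", "management", "regimen", "germane", "amenable")

#: rendered surface form per planted sex/gender lexicon term
SG_SURFACE = {
    "sex": "sex",
    "gender": "gender",
    "woman": "woman",
    "women": "women",
    "man": "man",
    "men": "men",
    "female": "female",
    "females": "females",
    "male": "male",
    "males": "males",
    "girl": "girl",
    "girls": "girls",
    "boy": "boy",
    "boys": "boys",
    "pregnan": "pregnant",
    "transg": "transgender",
}
HPV_SURFACE = ("human papillomavirus", "HPV", "HPV16", "HPV-positive tumors")

_STATUS_GROUP = {
    "Active, not recruiting": "ACTIVE_NOT_RECRUITING",
    "Completed": "COMPLETED",
    "Not yet recruiting": "NOT_YET_RECRUITING",
    "Recruiting": "RECRUITING_OR_INVITATION",
    "Enrolling by invitation": "RECRUITING_OR_INVITATION",
    "Unknown status": "UNKNOWN_OR_SUSPENDED",
    "Suspended": "UNKNOWN_OR_SUSPENDED",
    "Withdrawn": None,  # excluded upstream; no status group
    "Terminated": None,
}
_PHASE_GROUP = {
    "Early Phase 1": "EP1_P1",
    "Phase 1": "EP1_P1",
    "Phase 1/Phase 2": "P1_P2",
    "Phase 2": "P2_P3",
    "Phase 2/Phase 3": "P2_P3",
    "Phase 3": "P2_P3",
    "Phase 4": "P4",
    "N/A": "NOT_APPLICABLE",
    "": "NOT_APPLICABLE",
}

TRUTH_COLUMNS = [
    "nct_id", "included", "excluded_reason", "sg_category", "hpv_mention",
    "subsite_group", "study_type", "control_class", "randomization",
    "phase_group", "enrolment_group", "status_group", "submission_year",
]


@dataclass
class SynthParams:
    """Generator parameters; the defaults emulate the 2022 cohort structure."""

    n_studies: int = 1000
    seed: int = 0
    p_interventional: float = 0.84
    p_controlled_given_interventional: float = 0.86
    p_randomized_given_interventional: float = 0.38
    #: per-section probability of planting one S/G term
    sg_section_probs: dict[str, float] = dc_field(
        default_factory=lambda: {
            "brief_title": 0.002,
            "official_title": 0.005,
            "brief_summary": 0.015,
            "detailed_description": 0.020,
            "outcomes": 0.010,
            "design_groups": 0.001,
            "interventions": 0.002,
            "eligibility_population": 0.17,
            "eligibility_criteria": 0.52,
        }
    )
    p_hpv: float = 0.17
    p_subsite_A: float = 0.34
    enrolment_log_mean: float = 3.87
    enrolment_log_sd: float = 1.4
    p_enrolment_missing: float = 0.021
    phase_weights: dict[str, float] = dc_field(
        default_factory=lambda: {
            "Early Phase 1": 0.030,
            "Phase 1": 0.099,
            "Phase 1/Phase 2": 0.072,
            "Phase 2": 0.350,
            "Phase 2/Phase 3": 0.080,
            "Phase 3": 0.153,
            "Phase 4": 0.012,
            "N/A": 0.180,
            "": 0.024,
        }
    )
    status_weights: dict[str, float] = dc_field(
        default_factory=lambda: {
            "Withdrawn": 0.070,
            "Terminated": 0.070,
            "Active, not recruiting": 0.089,
            "Completed": 0.373,
            "Not yet recruiting": 0.056,
            "Recruiting": 0.183,
            "Enrolling by invitation": 0.020,
            "Unknown status": 0.111,
            "Suspended": 0.028,
        }
    )
    year_range: tuple[int, int] = (1999, 2022)
    #: per-year weight; default None = linear growth over the range
    year_weights: list[float] | None = None
    p_non_hnc: float = 0.08
    p_partial_hnc: float = 0.04
    p_single_sex: float = 0.004
    decoy_rate: float = 0.10

    def validate(self) -> None:
        probs = [
            self.p_interventional, self.p_controlled_given_interventional,
            self.p_randomized_given_interventional, self.p_hpv, self.p_subsite_A,
            self.p_enrolment_missing, self.p_non_hnc, self.p_partial_hnc,
            self.p_single_sex, self.decoy_rate, *self.sg_section_probs.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for name, weights in (("phase", self.phase_weights), ("status", self.status_weights)):
            vals = list(weights.values())
            if any(w < 0 for w in vals) or sum(vals) <= 0:
                raise ValueError(f"{name}_weights must be nonnegative and sum > 0")
        unknown = set(self.sg_section_probs) - set(ANALYSIS_SECTIONS + ELIGIBILITY_SECTIONS)
        if unknown:
            raise ValueError(f"unknown section ids in sg_section_probs: {sorted(unknown)}")


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _sentence_with_term(section: str, surface: str) -> str:
    if section in ELIGIBILITY_SECTIONS:
        return f"Participants who are {surface} require additional review before entry."
    return f"Outcomes will be stratified by {surface}."


def _generate_study(i: int, params: SynthParams, sg_terms: list[str]) -> tuple[StudyRecord, dict]:
    # per-study substream: draws never depend on generation order
    rng = np.random.default_rng([params.seed, i])
    nct_id = f"NCT{i + 1:08d}"

    u = rng.random()
    if u < params.p_non_hnc:
        hnc_kind = "none"
    elif u < params.p_non_hnc + params.p_partial_hnc:
        hnc_kind = "partial"
    else:
        hnc_kind = "full"
    subsite_a = bool(rng.random() < params.p_subsite_A)
    pool = CONDITIONS_SUBSITE_A if subsite_a else CONDITIONS_SUBSITE_B
    hnc_condition = pool[rng.integers(len(pool))]
    if hnc_kind == "none":
        conditions = [CONDITIONS_NON_HNC[rng.integers(len(CONDITIONS_NON_HNC))]]
        subsite_a = False
    elif hnc_kind == "partial":
        conditions = [hnc_condition, CONDITIONS_NON_HNC[rng.integers(len(CONDITIONS_NON_HNC))]]
    else:
        conditions = [hnc_condition]
    mesh_terms = [c.title() for c in conditions]

    status = _weighted_choice(rng, params.status_weights)
    single_sex = rng.random() < params.p_single_sex
    sex = EligibilitySex.ALL
    if single_sex:
        sex = EligibilitySex.MALE if rng.random() < 7 / 8 else EligibilitySex.FEMALE

    interventional = rng.random() < params.p_interventional
    if interventional:
        controlled = rng.random() < params.p_controlled_given_interventional
        randomized = rng.random() < params.p_randomized_given_interventional
        phase_raw = _weighted_choice(rng, params.phase_weights)
        allocation = "Randomized" if randomized else "Non-Randomized"
        drug = DRUGS[rng.integers(len(DRUGS))]
        if controlled:
            arms = [("Arm A", "Experimental"), ("Arm B", "Placebo Comparator")]
            if rng.random() < 0.3:
                arms.append(("Arm C", "Active Comparator"))
        else:
            arms = [("Cohort 1", "Other")] if rng.random() < 0.7 else []
        interventions = [(drug, f"Administration of {drug} at the protocol-specified dose.")]
    else:
        controlled = False
        randomized = False
        phase_raw = None
        allocation = None
        drug = DRUGS[rng.integers(len(DRUGS))]
        arms = []
        interventions = []

    missing_enrolment = rng.random() < params.p_enrolment_missing
    enrollment = None
    if not missing_enrolment:
        enrollment = max(1, int(round(rng.lognormal(params.enrolment_log_mean,
                                                    params.enrolment_log_sd))))

    first_year, last_year = params.year_range
    years = np.arange(first_year, last_year + 1)
    if params.year_weights is not None:
        yw = np.asarray(params.year_weights, dtype=float)
    else:
        yw = np.arange(1, len(years) + 1, dtype=float)  # linear rise
    year = int(years[rng.choice(len(years), p=yw / yw.sum())])
    submitted = date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))

    condition_text = conditions[0]
    sections: dict[str, str] = {
        "brief_title": f"Evaluation of {drug} for {condition_text}",
        "official_title": (
            f"A prospective clinical evaluation of {drug} in participants "
            f"with {condition_text}"
        ),
        "brief_summary": (
            f"This clinical investigation assesses the safety and activity of "
            f"{drug} in participants with {condition_text}."
        ),
        "detailed_description": (
            f"Participants receive {drug} according to the assigned schedule. "
            "Response is assessed at regular intervals."
        ),
        "outcomes": "Proportion of participants with confirmed response at 12 weeks.",
        "eligibility_population": f"Adults with histologically confirmed {condition_text}.",
        "eligibility_criteria": (
            "Inclusion: age 18 or older; adequate organ function. "
            "Exclusion: prior systemic therapy."
        ),
    }
    outcome_measure = "Objective response rate"
    group_extra = ""
    intervention_extra = ""

    # plant S/G terms section by section
    planted_sections: list[str] = []
    for section in ANALYSIS_SECTIONS + ELIGIBILITY_SECTIONS:
        p = params.sg_section_probs.get(section, 0.0)
        if rng.random() < p:
            term = sg_terms[rng.integers(len(sg_terms))]
            surface = SG_SURFACE.get(term, term)
            extra = _sentence_with_term(section, surface)
            if section == "design_groups":
                group_extra = f"Group stratified by {surface}"
            elif section == "interventions":
                intervention_extra = extra
            elif section == "outcomes":
                sections["outcomes"] += " " + extra
            else:
                sections[section] += " " + extra
            planted_sections.append(section)
    if set(planted_sections) & set(ANALYSIS_SECTIONS):
        sg_category = "ANALYTICAL"
    elif planted_sections:
        sg_category = "RECRUITMENT_ONLY"
    else:
        sg_category = "NO_MENTION"

    hpv = rng.random() < params.p_hpv
    if hpv:
        surface = HPV_SURFACE[rng.integers(len(HPV_SURFACE))]
        target = "brief_summary" if rng.random() < 0.5 else "detailed_description"
        sections[target] += f" {surface} status will be recorded."

    if rng.random() < params.decoy_rate:
        decoy = DECOY_WORDS[rng.integers(len(DECOY_WORDS))]
        target = ["brief_summary", "detailed_description", "eligibility_criteria"][
            rng.integers(3)
        ]
        sections[target] += f" The {decoy} component of care is documented."

    if group_extra:
        # observational studies may also carry design groups in the registry
        arms = arms + [(group_extra, arms[0][1] if arms else "Other")]
    if intervention_extra:
        if interventions:
            name, desc = interventions[0]
            interventions = [(name, desc + " " + intervention_extra)]
        else:
            interventions = [("protocol assessment", intervention_extra)]

    record = StudyRecord(
        nct_id=nct_id,
        brief_title=sections["brief_title"],
        official_title=sections["official_title"],
        brief_summary=sections["brief_summary"],
        detailed_description=sections["detailed_description"],
        conditions=conditions,
        mesh_terms=mesh_terms,
        eligibility_sex=sex,
        eligibility_population=sections["eligibility_population"],
        eligibility_criteria=sections["eligibility_criteria"],
        enrollment=enrollment,
        phase_raw=phase_raw,
        overall_status=status,
        study_type="Interventional" if interventional else "Observational",
        allocation=allocation,
        arms=arms,
        outcomes=[(outcome_measure, sections["outcomes"])],
        interventions=interventions,
        first_submitted=submitted,
        source=f"Center {1 + i % 17}",
    )

    status_group = _STATUS_GROUP[status]
    if hnc_kind != "full":
        included, reason = False, "non_hnc"
    elif status_group is None:
        included, reason = False, "status"
    elif single_sex:
        included, reason = False, "single_sex"
    else:
        included, reason = True, ""
    truth = {
        "nct_id": nct_id,
        "included": included,
        "excluded_reason": reason,
        "sg_category": sg_category,
        "hpv_mention": hpv,
        "subsite_group": "A_HPV_RELEVANT" if subsite_a and hnc_kind != "none" else "B_OTHER",
        "study_type": "INTERVENTIONAL" if interventional else "OBSERVATIONAL",
        "control_class": "CONTROLLED" if controlled else "UNCONTROLLED",
        "randomization": "RANDOMIZED" if randomized else "NON_RANDOMIZED",
        "phase_group": _PHASE_GROUP[phase_raw or ""] if interventional else "NOT_APPLICABLE",
        "enrolment_group": "GT_100" if (enrollment or 0) > 100 else "LE_100",
        "status_group": status_group or "",
        "submission_year": year,
    }
    return record, truth


def generate_registry(params: SynthParams) -> tuple[RegistryBundle, pd.DataFrame]:
    """Generate a seeded registry bundle and its planted truth labels.

    Deterministic given ``params.seed``; per-study substreams are derived
    from ``(seed, study index)`` so a study's draws do not depend on
    generation order.
    """
    params.validate()
    from .lexicons import sg_lexicon

    sg_terms = sg_lexicon().terms
    records: dict[str, StudyRecord] = {}
    truth_rows = []
    for i in range(params.n_studies):
        record, truth = _generate_study(i, params, sg_terms)
        records[record.nct_id] = record
        truth_rows.append(truth)
    last_year = params.year_range[1]
    bundle = RegistryBundle(studies=records, snapshot_date=date(last_year, 12, 31))
    return bundle, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def write_synthetic_registry(
    params: SynthParams, out_dir: str | Path
) -> tuple[RegistryBundle, pd.DataFrame]:
    """Generate and write the delimited tables plus ``truth_labels.csv``."""
    bundle, truth = generate_registry(params)
    out_dir = Path(out_dir)
    write_registry(bundle, out_dir)
    truth.to_csv(out_dir / "truth_labels.csv", index=False)
    return bundle, truth


def recovery_report(
    truth: pd.DataFrame, predicted: pd.DataFrame
) -> dict[str, dict[str, object]]:
    """Per-label confusion matrices and exact-agreement rates.

    ``truth`` and ``predicted`` must cover exactly the same NCT ids; the
    labels compared are the intersection of their columns (besides nct_id).
    """
    t_ids, p_ids = set(truth["nct_id"]), set(predicted["nct_id"])
    if t_ids != p_ids:
        diff = sorted(t_ids ^ p_ids)
        raise ValueError(f"id sets differ; symmetric difference: {diff}")
    t = truth.set_index("nct_id").sort_index()
    p = predicted.set_index("nct_id").sort_index()
    labels = [c for c in t.columns if c in p.columns and c != "nct_id"]
    report: dict[str, dict[str, object]] = {}
    for label in labels:
        tv = t[label].astype(str)
        pv = p[label].astype(str)
        confusion = pd.crosstab(tv, pv, rownames=["truth"], colnames=["predicted"])
        levels = sorted(set(confusion.index) | set(confusion.columns))
        confusion = confusion.reindex(index=levels, columns=levels, fill_value=0)
        report[label] = {
            "confusion": confusion,
            "agreement": float((tv == pv).mean()),
        }
    return report
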