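"""Derivation of the stratification labels used in the summary tables.

Each included study receives exactly one value of every label:
study type, controlled/uncontrolled, randomized/non-randomized, phase
group, enrolment group (dichotomized at 100 subjects, missing pooled with
<=100), status group and submission year.  Unknown registry vocabulary is
mapped to the most conservative group with a logged warning, never dropped,
so the labels stay exhaustive downstream.
"""

from __future__ import annotations

import logging
from enum import Enum

import pandas as pd

from .mention_tagging import MentionCategory, SubsiteGroup
from .registry_io import RegistryBundle, StudyRecord

log = logging.getLogger(__name__)


class StudyType(str, Enum):
    INTERVENTIONAL = "INTERVENTIONAL"
    OBSERVATIONAL = "OBSERVATIONAL"


class ControlClass(str, Enum):
    CONTROLLED = "CONTROLLED"
    UNCONTROLLED = "UNCONTROLLED"


class Randomization(str, Enum):
    RANDOMIZED = "RANDOMIZED"
    NON_RANDOMIZED = "NON_RANDOMIZED"


class PhaseGroup(str, Enum):
    EP1_P1 = "EP1_P1"
    P1_P2 = "P1_P2"
    P2_P3 = "P2_P3"
    P4 = "P4"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class EnrolmentGroup(str, Enum):
    LE_100 = "LE_100"
    GT_100 = "GT_100"


class StatusGroup(str, Enum):
    ACTIVE_NOT_RECRUITING = "ACTIVE_NOT_RECRUITING"
    COMPLETED = "COMPLETED"
    NOT_YET_RECRUITING = "NOT_YET_RECRUITING"
    RECRUITING_OR_INVITATION = "RECRUITING_OR_INVITATION"
    UNKNOWN_OR_SUSPENDED = "UNKNOWN_OR_SUSPENDED"


#: arm types that make an interventional study "controlled"
CONTROL_ARM_TYPES = frozenset(
    {"experimental", "active comparator", "placebo comparator", "sham comparator"}
)
#: arm types known not to qualify
NON_CONTROL_ARM_TYPES = frozenset({"no intervention", "other"})

_PHASE_MAP = {
    "early phase 1": PhaseGroup.EP1_P1,
    "phase 1": PhaseGroup.EP1_P1,
    "phase 1/phase 2": PhaseGroup.P1_P2,
    "phase 2": PhaseGroup.P2_P3,
    "phase 2/phase 3": PhaseGroup.P2_P3,
    "phase 3": PhaseGroup.P2_P3,
    "phase 4": PhaseGroup.P4,
    "n/a": PhaseGroup.NOT_APPLICABLE,
    "not applicable": PhaseGroup.NOT_APPLICABLE,
}

_STATUS_MAP = {
    "active, not recruiting": StatusGroup.ACTIVE_NOT_RECRUITING,
    "completed": StatusGroup.COMPLETED,
    "not yet recruiting": StatusGroup.NOT_YET_RECRUITING,
    "recruiting": StatusGroup.RECRUITING_OR_INVITATION,
    "enrolling by invitation": StatusGroup.RECRUITING_OR_INVITATION,
    "unknown status": StatusGroup.UNKNOWN_OR_SUSPENDED,
    "unknown": StatusGroup.UNKNOWN_OR_SUSPENDED,
    "suspended": StatusGroup.UNKNOWN_OR_SUSPENDED,
}


def classify_study_type(study_type_raw: str) -> StudyType:
    """Interventional vs observational; "Observational [Patient Registry]"
    merges into observational."""
    low = study_type_raw.strip().lower()
    if low.startswith("observational"):
        return StudyType.OBSERVATIONAL
    if low != "interventional":
        log.warning("unknown study type %r; treated as interventional", study_type_raw)
    return StudyType.INTERVENTIONAL


def classify_control(arms: list[tuple[str, str]]) -> ControlClass:
    """Controlled iff at least one arm is typed Experimental / Active
    Comparator / Placebo Comparator / Sham Comparator.  Arm order is
    irrelevant; an empty arm list is uncontrolled."""
    for _, arm_type in arms:
        low = arm_type.strip().lower()
        if low in CONTROL_ARM_TYPES:
            return ControlClass.CONTROLLED
        if low and low not in NON_CONTROL_ARM_TYPES:
            log.warning("unknown arm type %r; treated as non-qualifying", arm_type)
    return ControlClass.UNCONTROLLED


def classify_randomization(allocation: str | None) -> Randomization:
    """Randomized iff the allocation field reads "Randomized" (any case)."""
    if allocation is not None and allocation.strip().lower() == "randomized":
        return Randomization.RANDOMIZED
    return Randomization.NON_RANDOMIZED


def phase_group(phase_raw: str | None, study_type: StudyType) -> PhaseGroup:
    """Collapse the registry phase vocabulary into the five reported groups.

    Observational studies are always NOT_APPLICABLE; missing or unknown
    phase labels pool with NOT_APPLICABLE.
    """
    if study_type is StudyType.OBSERVATIONAL:
        return PhaseGroup.NOT_APPLICABLE
    if phase_raw is None or not phase_raw.strip():
        return PhaseGroup.NOT_APPLICABLE
    key = phase_raw.strip().lower()
    if key not in _PHASE_MAP:
        log.warning("unknown phase label %r; treated as Not Applicable", phase_raw)
        return PhaseGroup.NOT_APPLICABLE
    return _PHASE_MAP[key]


def enrolment_group(enrollment: int | None) -> EnrolmentGroup:
    """Dichotomize planned sample size at 100; missing pools with <=100."""
    if enrollment is None or enrollment <= 100:
        return EnrolmentGroup.LE_100
    return EnrolmentGroup.GT_100


def status_group(overall_status: str) -> StatusGroup:
    """Collapse recruitment statuses into the five reported groups.

    Withdrawn/Terminated never reach this point (excluded upstream);
    unrecognized statuses pool with Unknown/Suspended.
    """
    key = overall_status.strip().lower()
    if key not in _STATUS_MAP:
        log.warning("unknown status %r; treated as Unknown/Suspended", overall_status)
        return StatusGroup.UNKNOWN_OR_SUSPENDED
    return _STATUS_MAP[key]


def submission_year(record: StudyRecord) -> int | None:
    return record.first_submitted.year if record.first_submitted else None


def derive_labels(
    bundle: RegistryBundle,
    tags: pd.DataFrame,
    included_ids: list[str] | None = None,
) -> pd.DataFrame:
    """One row per study with every derived label, merged with the tags.

    ``tags`` is the output of :func:`hncmeta.mention_tagging.tag_cohort`.
    """
    tag_by_id = tags.set_index("nct_id")
    ids = list(included_ids) if included_ids is not None else tag_by_id.index.tolist()
    rows = []
    for nct_id in ids:
        rec = bundle[nct_id]
        stype = classify_study_type(rec.study_type)
        tag = tag_by_id.loc[nct_id]
        rows.append(
            {
                "nct_id": nct_id,
                "sg_category": MentionCategory(tag["sg_category"]).value,
                "hpv_mention": bool(tag["hpv_mention"]),
                "subsite_group": SubsiteGroup(tag["subsite_group"]).value,
                "study_type": stype.value,
                "control_class": classify_control(rec.arms).value,
                "randomization": classify_randomization(rec.allocation).value,
                "phase_group": phase_group(rec.phase_raw, stype).value,
                "enrolment_group": enrolment_group(rec.enrollment).value,
                "status_group": status_group(rec.overall_status).value,
                "submission_year": submission_year(rec),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "nct_id", "sg_category", "hpv_mention", "subsite_group", "study_type",
            "control_class", "randomization", "phase_group", "enrolment_group",
            "status_group", "submission_year",
        ],
    )
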