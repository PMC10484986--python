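"""Reading, validating and writing AACT-style registry table bundles.

The public AACT export of ClinicalTrials.gov is a set of relational tables
keyed by NCT identifier.  :func:`load_registry` reads the delimited text
export of those tables, joins the auxiliary tables onto the ``studies``
table and assembles one :class:`StudyRecord` per study.
:func:`section_map` then exposes the free-text registration fields the
classifiers search, split into ANALYSIS sections (titles, summaries,
outcome measures, arm-group titles, intervention descriptions) and
ELIGIBILITY sections (eligibility population and criteria text).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)


class EligibilitySex(str, Enum):
    ALL = "ALL"
    MALE = "MALE"
    FEMALE = "FEMALE"


#: sections searched for "analytical" mentions, in stable order
ANALYSIS_SECTIONS: tuple[str, ...] = (
    "brief_title",
    "official_title",
    "brief_summary",
    "detailed_description",
    "outcomes",
    "design_groups",
    "interventions",
)
#: sections that count only as recruitment-level mentions
ELIGIBILITY_SECTIONS: tuple[str, ...] = ("eligibility_population", "eligibility_criteria")
ALL_SECTIONS: tuple[str, ...] = ANALYSIS_SECTIONS + ELIGIBILITY_SECTIONS

#: table name -> default file name of the delimited export
TABLE_FILES: dict[str, str] = {
    "studies": "studies.csv",
    "conditions": "conditions.csv",
    "browse_conditions": "browse_conditions.csv",
    "eligibilities": "eligibilities.csv",
    "designs": "designs.csv",
    "design_groups": "design_groups.csv",
    "design_outcomes": "design_outcomes.csv",
    "interventions": "interventions.csv",
    "brief_summaries": "brief_summaries.csv",
    "detailed_descriptions": "detailed_descriptions.csv",
}


@dataclass
class StudyRecord:
    """One registered study with its free-text sections and design fields."""

    nct_id: str
    brief_title: str = ""
    official_title: str = ""
    brief_summary: str = ""
    detailed_description: str = ""
    conditions: list[str] = field(default_factory=list)
    mesh_terms: list[str] = field(default_factory=list)
    eligibility_sex: EligibilitySex = EligibilitySex.ALL
    eligibility_population: str = ""
    eligibility_criteria: str = ""
    enrollment: int | None = None
    phase_raw: str | None = None
    overall_status: str = ""
    study_type: str = ""
    allocation: str | None = None
    arms: list[tuple[str, str]] = field(default_factory=list)  # (title, arm_type)
    outcomes: list[tuple[str, str]] = field(default_factory=list)  # (measure, description)
    interventions: list[tuple[str, str]] = field(default_factory=list)  # (name, description)
    first_submitted: date | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.nct_id:
            raise ValueError("nct_id must be non-empty")
        if self.enrollment is not None and self.enrollment < 0:
            raise ValueError(f"{self.nct_id}: enrollment must be >= 0")

    def all_conditions(self) -> list[str]:
        """Free-text condition names plus MeSH browse-condition names."""
        return list(self.conditions) + list(self.mesh_terms)


@dataclass
class RegistryBundle:
    """All study records of one registry snapshot, keyed by NCT id."""

    studies: dict[str, StudyRecord]
    snapshot_date: date | None = None

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterable[StudyRecord]:
        return iter(self.studies.values())

    def __getitem__(self, nct_id: str) -> StudyRecord:
        return self.studies[nct_id]


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _group(df: pd.DataFrame | None) -> dict[str, pd.DataFrame]:
    if df is None or "nct_id" not in (df.columns if df is not None else []):
        return {}
    return {k: g for k, g in df.groupby("nct_id", sort=False)}


def _parse_sex(raw: str, nct_id: str) -> EligibilitySex:
    val = raw.strip().lower()
    if val in ("", "all"):
        if val == "":
            log.warning("%s: eligibility sex absent; treated as All", nct_id)
        return EligibilitySex.ALL
    if val == "male":
        return EligibilitySex.MALE
    if val == "female":
        return EligibilitySex.FEMALE
    log.warning("%s: unknown eligibility sex %r; treated as All", nct_id, raw)
    return EligibilitySex.ALL


def _parse_date(raw: str) -> date | None:
    raw = raw.strip()
    if not raw:
        return None
    return pd.Timestamp(raw).date()


def _parse_enrollment(raw: str, nct_id: str) -> int | None:
    raw = raw.strip()
    if not raw:
        return None
    try:
        value = int(float(raw))
    except ValueError:
        log.warning("%s: unparseable enrollment %r; treated as missing", nct_id, raw)
        return None
    return value


def load_registry(
    table_paths: Mapping[str, str | Path] | str | Path,
    sep: str = ",",
    snapshot_date: date | None = None,
) -> RegistryBundle:
    """Assemble a :class:`RegistryBundle` from delimited table files.

    ``table_paths`` is either a mapping of table name to file path or a
    directory containing the conventionally named files (``studies.csv``,
    ``conditions.csv``, ...).  The ``studies`` table is required; any other
    table may be absent, in which case the corresponding record fields are
    empty.  Duplicate NCT ids are a fatal validation error.
    """
    if isinstance(table_paths, (str, Path)):
        root = Path(table_paths)
        table_paths = {
            name: root / fname for name, fname in TABLE_FILES.items() if (root / fname).exists()
        }
    table_paths = dict(table_paths)

    if "studies" not in table_paths:
        raise FileNotFoundError("registry bundle is missing the required 'studies' table")
    tables: dict[str, pd.DataFrame] = {}
    for name, path in table_paths.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"table {name!r}: file not found: {path}")
        tables[name] = _read_table(path, sep)

    studies = tables["studies"]
    if "nct_id" not in studies.columns:
        raise ValueError("studies table has no nct_id column")
    dupes = studies["nct_id"][studies["nct_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate nct_id in studies table: {dupes}")

    by_id = {name: _group(tables.get(name)) for name in TABLE_FILES if name != "studies"}

    def col(row: pd.Series, name: str) -> str:
        return str(row[name]).strip() if name in row.index else ""

    def aux_rows(table: str, nct_id: str) -> pd.DataFrame | None:
        return by_id.get(table, {}).get(nct_id)

    def aux_col(table: str, nct_id: str, column: str) -> list[str]:
        g = aux_rows(table, nct_id)
        if g is None or column not in g.columns:
            return []
        return [str(v).strip() for v in g[column] if str(v).strip()]

    def aux_pairs(table: str, nct_id: str, c1: str, c2: str) -> list[tuple[str, str]]:
        g = aux_rows(table, nct_id)
        if g is None:
            return []
        out = []
        for _, r in g.iterrows():
            a = str(r[c1]).strip() if c1 in g.columns else ""
            b = str(r[c2]).strip() if c2 in g.columns else ""
            if a or b:
                out.append((a, b))
        return out

    records: dict[str, StudyRecord] = {}
    for _, row in studies.iterrows():
        nct_id = col(row, "nct_id")
        elig = aux_rows("eligibilities", nct_id)
        sex_raw = pop = crit = ""
        if elig is not None and len(elig):
            first = elig.iloc[0]
            sex_raw = str(first.get("gender", "")).strip()
            pop = str(first.get("population", "")).strip()
            crit = str(first.get("criteria", "")).strip()
        designs = aux_rows("designs", nct_id)
        allocation = None
        if designs is not None and len(designs) and "allocation" in designs.columns:
            alloc_raw = str(designs.iloc[0]["allocation"]).strip()
            allocation = alloc_raw or None

        phase = col(row, "phase") or None
        status = col(row, "overall_status")
        record = StudyRecord(
            nct_id=nct_id,
            brief_title=col(row, "brief_title"),
            official_title=col(row, "official_title"),
            brief_summary="\n".join(aux_col("brief_summaries", nct_id, "description")),
            detailed_description="\n".join(
                aux_col("detailed_descriptions", nct_id, "description")
            ),
            conditions=aux_col("conditions", nct_id, "name"),
            mesh_terms=aux_col("browse_conditions", nct_id, "mesh_term"),
            eligibility_sex=_parse_sex(sex_raw, nct_id),
            eligibility_population=pop,
            eligibility_criteria=crit,
            enrollment=_parse_enrollment(col(row, "enrollment"), nct_id),
            phase_raw=phase,
            overall_status=status,
            study_type=col(row, "study_type"),
            allocation=allocation,
            arms=aux_pairs("design_groups", nct_id, "title", "group_type"),
            outcomes=aux_pairs("design_outcomes", nct_id, "measure", "description"),
            interventions=aux_pairs("interventions", nct_id, "name", "description"),
            first_submitted=_parse_date(col(row, "study_first_submitted_date")),
            source=col(row, "source"),
        )
        records[nct_id] = record
    return RegistryBundle(studies=records, snapshot_date=snapshot_date)


def section_map(record: StudyRecord) -> dict[str, str]:
    """Return the targeted free-text sections of a record, keyed by section id.

    Total and deterministic: every section id is present for every record
    (empty string when the underlying field is empty).  List-valued sections
    are concatenated with newlines so no whole-word match can span entries.
    Arm-group titles only (not descriptions) enter the ``design_groups``
    section; intervention *descriptions* form the ``interventions`` section.
    """
    outcome_parts = [part for m, d in record.outcomes for part in (m, d) if part]
    return {
        "brief_title": record.brief_title,
        "official_title": record.official_title,
        "brief_summary": record.brief_summary,
        "detailed_description": record.detailed_description,
        "outcomes": "\n".join(outcome_parts),
        "design_groups": "\n".join(t for t, _ in record.arms if t),
        "interventions": "\n".join(d for _, d in record.interventions if d),
        "eligibility_population": record.eligibility_population,
        "eligibility_criteria": record.eligibility_criteria,
    }


def write_registry(bundle: RegistryBundle, out_dir: str | Path, sep: str = ",") -> dict[str, Path]:
    """Write a bundle back to per-table delimited files (inverse of load)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: dict[str, list[dict[str, object]]] = {name: [] for name in TABLE_FILES}
    for rec in bundle:
        rows["studies"].append(
            {
                "nct_id": rec.nct_id,
                "brief_title": rec.brief_title,
                "official_title": rec.official_title,
                "overall_status": rec.overall_status,
                "phase": rec.phase_raw or "",
                "enrollment": "" if rec.enrollment is None else rec.enrollment,
                "study_type": rec.study_type,
                "source": rec.source,
                "study_first_submitted_date": (
                    rec.first_submitted.isoformat() if rec.first_submitted else ""
                ),
            }
        )
        for name in rec.conditions:
            rows["conditions"].append({"nct_id": rec.nct_id, "name": name})
        for term in rec.mesh_terms:
            rows["browse_conditions"].append({"nct_id": rec.nct_id, "mesh_term": term})
        rows["eligibilities"].append(
            {
                "nct_id": rec.nct_id,
                "gender": rec.eligibility_sex.value.capitalize()
                if rec.eligibility_sex != EligibilitySex.ALL
                else "All",
                "population": rec.eligibility_population,
                "criteria": rec.eligibility_criteria,
            }
        )
        if rec.allocation is not None:
            rows["designs"].append({"nct_id": rec.nct_id, "allocation": rec.allocation})
        for title, arm_type in rec.arms:
            rows["design_groups"].append(
                {"nct_id": rec.nct_id, "title": title, "group_type": arm_type}
            )
        for measure, desc in rec.outcomes:
            rows["design_outcomes"].append(
                {"nct_id": rec.nct_id, "measure": measure, "description": desc}
            )
        for name, desc in rec.interventions:
            rows["interventions"].append(
                {"nct_id": rec.nct_id, "name": name, "description": desc}
            )
        if rec.brief_summary:
            rows["brief_summaries"].append(
                {"nct_id": rec.nct_id, "description": rec.brief_summary}
            )
        if rec.detailed_description:
            rows["detailed_descriptions"].append(
                {"nct_id": rec.nct_id, "description": rec.detailed_description}
            )

    columns = {
        "studies": [
            "nct_id", "brief_title", "official_title", "overall_status", "phase",
            "enrollment", "study_type", "source", "study_first_submitted_date",
        ],
        "conditions": ["nct_id", "name"],
        "browse_conditions": ["nct_id", "mesh_term"],
        "eligibilities": ["nct_id", "gender", "population", "criteria"],
        "designs": ["nct_id", "allocation"],
        "design_groups": ["nct_id", "title", "group_type"],
        "design_outcomes": ["nct_id", "measure", "description"],
        "interventions": ["nct_id", "name", "description"],
        "brief_summaries": ["nct_id", "description"],
        "detailed_descriptions": ["nct_id", "description"],
    }
    written: dict[str, Path] = {}
    for name, fname in TABLE_FILES.items():
        path = out_dir / fname
        pd.DataFrame(rows[name], columns=columns[name]).to_csv(
            path, sep=sep, index=False, encoding="utf-8"
        )
        written[name] = path
    return written


def study_table(bundle: RegistryBundle) -> pd.DataFrame:
    """Flatten a bundle to one row per study (sections + structured fields)."""
    rows = []
    for rec in bundle:
        row: dict[str, object] = {"nct_id": rec.nct_id}
        row.update(section_map(rec))
        row.update(
            {
                "conditions": "|".join(rec.conditions),
                "mesh_terms": "|".join(rec.mesh_terms),
                "eligibility_sex": rec.eligibility_sex.value,
                "enrollment": rec.enrollment,
                "phase_raw": rec.phase_raw,
                "overall_status": rec.overall_status,
                "study_type": rec.study_type,
                "allocation": rec.allocation,
                "first_submitted": rec.first_submitted,
                "source": rec.source,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
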