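"""One-command orchestration of the full analysis.

``run_all`` executes the stages in order — load registry, select cohort,
tag mentions, derive labels, summary tables, trends — writing each stage's
output as delimited text plus a JSON manifest with input checksums and
every test/odds-ratio computed.  Any stage error aborts the run with the
stage name; partially written outputs are removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from . import __version__
from .association_stats import (
    mention_odds_ratio,
    summarize_by_mention,
)
from .cohort_selection import select_cohort, gate_table
from .design_classification import derive_labels
from .lexicons import hpv_lexicon, load_lexicon, sg_lexicon, subsite_lexicon
from .mention_tagging import tag_cohort
from .registry_io import RegistryBundle, load_registry
from .trend_analysis import compare_year_proportions, yearly_series

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    registry_dir: Path
    output_dir: Path
    lexicon_dir: Path | None = None  # None = built-in lexicons
    snapshot_date: date | None = None
    sep: str = ","
    options: dict[str, object] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        snapshot = raw.get("snapshot_date")
        if isinstance(snapshot, str):
            snapshot = date.fromisoformat(snapshot)
        return cls(
            registry_dir=Path(raw["registry_dir"]),
            output_dir=Path(raw["output_dir"]),
            lexicon_dir=Path(raw["lexicon_dir"]) if raw.get("lexicon_dir") else None,
            snapshot_date=snapshot,
            sep=raw.get("sep", ","),
            options=raw.get("options", {}) or {},
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _lexicons(config: RunConfig):
    if config.lexicon_dir is None:
        return sg_lexicon(), hpv_lexicon(), subsite_lexicon()
    lex_dir = Path(config.lexicon_dir)
    if not lex_dir.is_dir():
        raise FileNotFoundError(f"lexicon directory not found: {lex_dir}")
    return (
        load_lexicon(lex_dir / "sg_terms.txt"),
        load_lexicon(lex_dir / "hpv_terms.txt"),
        load_lexicon(lex_dir / "subsite_terms.txt"),
    )


def top_sources(bundle: RegistryBundle, ids: list[str], k: int = 10) -> pd.DataFrame:
    """Frequency report of the most common study sources (lead organizations)."""
    counts = pd.Series([bundle[i].source for i in ids if bundle[i].source]).value_counts()
    frame = counts.head(k).rename_axis("source").reset_index(name="n")
    frame["pct"] = 100.0 * frame["n"] / len(ids) if ids else float("nan")
    return frame


def _or_entry(result) -> dict[str, object]:
    return {
        "estimate": round(result.estimate, 4),
        "ci_low": round(result.ci_low, 4),
        "ci_high": round(result.ci_high, 4),
        "reference_row": result.reference_row,
        "haldane_corrected": result.haldane_corrected,
    }


def run_all(config: RunConfig) -> dict[str, object]:
    """Run every stage; returns (and writes) the results manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict[str, object] = {
        "version": __version__,
        "config": {
            "registry_dir": str(config.registry_dir),
            "output_dir": str(out_dir),
            "lexicon_dir": str(config.lexicon_dir) if config.lexicon_dir else None,
            "snapshot_date": config.snapshot_date.isoformat()
            if config.snapshot_date
            else None,
        },
        "stages": [],
    }

    def emit(name: str, frame: pd.DataFrame) -> Path:
        path = out_dir / name
        frame.to_csv(path, index=False)
        written.append(path)
        return path

    def stage_done(name: str, **info: object) -> None:
        manifest["stages"].append({"stage": name, **info})
        log.info("stage %s: %s", name, info)

    try:
        stage = "load_registry"
        bundle = load_registry(config.registry_dir, sep=config.sep,
                               snapshot_date=config.snapshot_date)
        registry_dir = Path(config.registry_dir)
        manifest["input_checksums"] = {
            p.name: _sha256(p) for p in sorted(registry_dir.glob("*.csv"))
        }
        stage_done(stage, n_studies=len(bundle))

        stage = "select_cohort"
        report = select_cohort(bundle)
        emit("cohort.csv", gate_table(bundle))
        (out_dir / "cohort_report.json").write_text(
            json.dumps(report.to_dict(), indent=2), encoding="utf-8"
        )
        written.append(out_dir / "cohort_report.json")
        stage_done(stage, **{k: v for k, v in report.to_dict().items() if k != "included_ids"})

        stage = "tag_mentions"
        sg_lex, hpv_lex, sub_lex = _lexicons(config)
        tags = tag_cohort(bundle, report.included_ids, sg_lex, hpv_lex, sub_lex)
        emit("labels.csv", tags)
        stage_done(stage, n_tagged=len(tags))

        stage = "derive_labels"
        labels = derive_labels(bundle, tags, report.included_ids)
        emit("study_labels.csv", labels)
        stage_done(stage, n_labeled=len(labels))

        stage = "run_tables"
        interventional = labels["study_type"] == "INTERVENTIONAL"
        table1 = pd.concat(
            [
                summarize_by_mention(
                    labels,
                    ["study_type", "status_group", "enrolment_group",
                     "hpv_mention", "subsite_group"],
                ),
                summarize_by_mention(labels, ["phase_group"], filter=interventional),
            ],
            ignore_index=True,
        )
        emit("table1.csv", table1)
        table2_parts = []
        for control_class in ("CONTROLLED", "UNCONTROLLED"):
            part = summarize_by_mention(
                labels,
                ["study_type", "status_group", "enrolment_group",
                 "hpv_mention", "phase_group"],
                filter=labels["control_class"] == control_class,
            )
            part.insert(0, "control_class", control_class)
            table2_parts.append(part)
        emit("table2.csv", pd.concat(table2_parts, ignore_index=True))
        table3_parts = []
        for subsite in ("A_HPV_RELEVANT", "B_OTHER"):
            part = summarize_by_mention(
                labels,
                ["status_group", "study_type", "enrolment_group",
                 "sg_category", "phase_group"],
                col_var="hpv_mention",
                filter=labels["subsite_group"] == subsite,
            )
            part.insert(0, "subsite_group", subsite)
            table3_parts.append(part)
        emit("table3.csv", pd.concat(table3_parts, ignore_index=True))

        odds_ratios: dict[str, object] = {}
        try:
            odds_ratios["mention_interventional_vs_observational"] = _or_entry(
                mention_odds_ratio(labels, "study_type", "INTERVENTIONAL", "OBSERVATIONAL")
            )
            odds_ratios["mention_le100_vs_gt100"] = _or_entry(
                mention_odds_ratio(labels, "enrolment_group", "LE_100", "GT_100")
            )
            odds_ratios["mention_p2p3_vs_ep1p1"] = _or_entry(
                mention_odds_ratio(labels, "phase_group", "P2_P3", "EP1_P1",
                                   filter=interventional)
            )
        except (ValueError, KeyError) as err:
            log.warning("odds ratio skipped: %s", err)
        manifest["odds_ratios"] = odds_ratios
        emit("sources.csv", top_sources(bundle, report.included_ids))
        stage_done(stage, n_tables=3, n_odds_ratios=len(odds_ratios))

        stage = "run_trends"
        snapshot_year = config.snapshot_date.year if config.snapshot_date else None
        sg_series = yearly_series(labels, "sg_category", snapshot_year=snapshot_year)
        hpv_series = yearly_series(labels, "hpv_mention", snapshot_year=snapshot_year)
        trends = sg_series.counts.add_prefix("sg_").join(
            hpv_series.counts.add_prefix("hpv_"), how="outer"
        )
        trends.index.name = "year"
        path = out_dir / "trends.csv"
        trends.to_csv(path)
        written.append(path)
        comparison: dict[str, object] = {}
        year1, year2 = config.options.get("compare_years", (2010, 2020))
        try:
            result = compare_year_proportions(sg_series, "ANALYTICAL", year1, year2)
            comparison = {
                "years": [year1, year2],
                "stratum": "ANALYTICAL",
                "p_value": result.p_value,
                "method": result.method.value,
            }
        except (KeyError, ValueError) as err:
            log.warning("year comparison skipped: %s", err)
        manifest["year_comparison"] = comparison
        stage_done(stage, n_years=len(sg_series.years))
    except Exception as err:  # noqa: BLE001 - report stage, clean partial outputs
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(err, StageError):
            raise
        raise StageError(stage, err) from err

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=_json_default),
                             encoding="utf-8")
    return manifest


def _json_default(obj: object) -> object:
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, (pd.Timestamp, date)):
        return str(obj)
    return str(obj)
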