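"""End-to-end orchestration: load → dedup → filter → link → extract →
detect → classify → report.

The pipeline mirrors the standard spontaneous-report analysis flow:
drug and reaction tables are read under a dialect, duplicate report
versions are removed, only suspected-drug records are kept, tables are
linked by case id into the pair universe, target PTs are extracted,
disproportionality signals are detected over the full universe, and
signal drugs are classified by therapeutic category (antineoplastics
excluded) and cross-tabulated against package-insert annotations.

Every stage count is recorded in a :class:`RunManifest` sufficient to
redraw the analysis flow chart, and all outputs are deterministic
functions of the inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from . import classify as jclassify
from . import io as jio
from .classify import CategoryMap, InsertAnnotation
from .pt import (
    PTQuery,
    default_pt_set,
    load_pt_queries,
    pt_family,
    summaries_to_frame,
    summarize_pt_counts,
)
from .stats import (
    ContingencyTable,
    DetectionConfig,
    SignalCriteria,
    SignalMetrics,
    SignalResult,
    detect_signals,
    results_to_frame,
)

logger = logging.getLogger("jadersig")


class RunConfig(BaseModel):
    """Declarative description of one pipeline run."""

    drug_table: str
    reac_table: str
    dialect: str = "japanese"
    pt_query_file: str | None = None  # None -> packaged default PT set
    match_on: Literal["code", "name", "either"] = "either"
    dedup_strategy: Literal["latest_version", "first_seen"] = "latest_version"
    unit: Literal["triple", "row"] = "triple"
    ci_low_gt: float = Field(default=1.0, gt=0)
    prr_min: float = Field(default=2.0, gt=0)
    chi2_min: float = Field(default=4.0, gt=0)
    n_min: int = Field(default=3, gt=0)
    yates: bool = True
    zero_cell_policy: Literal["undefined", "haldane"] = "undefined"
    category_map: str | None = None
    annotation: str | None = None
    out_dir: str = "jadersig_out"
    seed: int = 0  # only simulation subcommands draw randomness

    def detection_config(self) -> DetectionConfig:
        return DetectionConfig(
            criteria=SignalCriteria(
                ci_low_gt=self.ci_low_gt,
                prr_min=self.prr_min,
                chi2_min=self.chi2_min,
                n_min=self.n_min,
            ),
            yates=self.yates,
            zero_cell_policy=self.zero_cell_policy,
            match_on=self.match_on,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-stage record counts plus provenance; redraws the flow chart."""

    software_version: str = __version__
    config_hash: str = ""
    rows_read: dict = field(default_factory=dict)
    rows_after_dedup: dict = field(default_factory=dict)
    cases_after_dedup: dict = field(default_factory=dict)
    suspected_records: int = 0
    n_pairs: int = 0
    n_target_pairs: int = 0
    pairs_per_pt: dict = field(default_factory=dict)
    candidates_tested: int = 0
    signals_per_pt: dict = field(default_factory=dict)
    signals_total: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def _load_queries(config: RunConfig) -> list[PTQuery]:
    if config.pt_query_file:
        return load_pt_queries(config.pt_query_file)
    return default_pt_set()


def build_pair_universe(config: RunConfig) -> tuple[jio.PairUniverse, RunManifest]:
    """Stages 1–4: read, deduplicate, filter to suspected, link."""
    manifest = RunManifest(config_hash=config.config_hash())
    drug_raw = jio.read_table(config.drug_table, "drug", config.dialect)
    reac_raw = jio.read_table(config.reac_table, "reac", config.dialect)
    manifest.rows_read = {"drug": len(drug_raw), "reac": len(reac_raw)}
    logger.info("read %d drug rows, %d reaction rows", len(drug_raw), len(reac_raw))

    drug = jio.deduplicate_cases(drug_raw, config.dedup_strategy)
    reac = jio.deduplicate_cases(reac_raw, config.dedup_strategy)
    manifest.rows_after_dedup = {"drug": len(drug), "reac": len(reac)}
    manifest.cases_after_dedup = {
        "drug": int(drug["case_id"].nunique()) if len(drug) else 0,
        "reac": int(reac["case_id"].nunique()) if len(reac) else 0,
    }
    suspected = jio.filter_suspected(drug)
    manifest.suspected_records = len(suspected)
    logger.info("deduplicated to %s cases; %d suspected records",
                manifest.cases_after_dedup, len(suspected))

    universe = jio.link_drug_event(suspected, reac, unit=config.unit)
    manifest.n_pairs = universe.n_total
    logger.info("linked pair universe: %d pairs", universe.n_total)
    return universe, manifest


def run_pipeline(config: RunConfig) -> tuple[RunManifest, list[SignalResult]]:
    """Execute the full flow and write all outputs under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True), encoding="utf-8"
    )

    universe, manifest = build_pair_universe(config)
    queries = _load_queries(config)

    from .pt import extract_target_pairs

    subset = extract_target_pairs(universe, queries, config.match_on)
    manifest.n_target_pairs = subset.n_total
    summaries = summarize_pt_counts(universe, queries, config.match_on)
    manifest.pairs_per_pt = {s.pt_name: s.n_reports for s in summaries}

    results = detect_signals(universe, queries, config.detection_config())
    manifest.candidates_tested = len(results)
    per_pt: dict[str, int] = {q.pt_name: 0 for q in queries}
    for r in results:
        if r.signal:
            per_pt[r.pt_name] += 1
    manifest.signals_per_pt = per_pt
    manifest.signals_total = sum(per_pt.values())
    logger.info("tested %d candidates, %d signals", len(results), manifest.signals_total)

    universe.to_tsv(out / "pairs.tsv")
    subset.to_tsv(out / "target_pairs.tsv")
    summaries_to_frame(summaries).to_csv(
        out / "pt_summary.tsv", sep="\t", index=False, lineterminator="\n"
    )
    write_report_tables(results, manifest, config, out)
    manifest.to_json(out / "manifest.json")
    return manifest, results


_REPORT_FLOATS = ("ror", "ci_low", "ci_high", "prr", "chi2")


def _format_report_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _REPORT_FLOATS:
        out[col] = out[col].map(lambda v: f"{v:.4g}" if pd.notna(v) else "NA")
    return out


def signal_results_to_json(results: Sequence[SignalResult], path: str | Path) -> None:
    """Full-precision machine-readable sidecar for the signals table."""
    frame = results_to_frame(results)
    records = json.loads(frame.to_json(orient="records"))
    Path(path).write_text(
        json.dumps(records, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def signal_results_from_json(path: str | Path) -> list[SignalResult]:
    records = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for r in records:
        nan = float("nan")
        metrics = SignalMetrics(
            ror=r["ror"] if r["ror"] is not None else nan,
            ci_low=r["ci_low"] if r["ci_low"] is not None else nan,
            ci_high=r["ci_high"] if r["ci_high"] is not None else nan,
            prr=r["prr"] if r["prr"] is not None else nan,
            chi2=r["chi2"] if r["chi2"] is not None else nan,
            n=r["n"],
        )
        out.append(
            SignalResult(
                drug_name=r["drug_name"],
                pt_name=r["pt_name"],
                table=ContingencyTable(r["a"], r["b"], r["c"], r["d"]),
                metrics=metrics,
                criterion_a=r["criterion_a"],
                criterion_b=r["criterion_b"],
            )
        )
    return out


def write_report_tables(
    results: Sequence[SignalResult],
    manifest: RunManifest,
    config: RunConfig,
    out_dir: str | Path,
) -> None:
    """Write the signal table, per-PT category summaries, multi-PT
    overlap and insert-annotation cross-tab.

    Report TSVs round floats to 4 significant digits; the JSON sidecar
    keeps full precision.  With zero signals the files are still valid
    (headers only where no body rows exist).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = results_to_frame(results)
    _format_report_frame(frame).to_csv(
        out / "signals.tsv", sep="\t", index=False, lineterminator="\n"
    )
    signal_results_to_json(results, out / "signals.json")

    flagged = [r for r in results if r.signal]
    if config.category_map:
        cmap = CategoryMap.from_csv(config.category_map)
        partition = jclassify.exclude_antineoplastics(flagged, cmap)
        pd.DataFrame(
            {
                "drug_name": [s.drug_name for s in partition.excluded],
                "pt_name": [s.pt_name for s in partition.excluded],
            }
        ).to_csv(out / "excluded_antineoplastics.tsv", sep="\t", index=False,
                 lineterminator="\n")
        pd.DataFrame(
            {"drug_name": [s.drug_name for s in partition.unresolved]}
        ).drop_duplicates().to_csv(out / "unresolved_category.tsv", sep="\t",
                                   index=False, lineterminator="\n")
        for pt in sorted({s.pt_name for s in partition.kept}):
            rows = [s for s in partition.kept if s.pt_name == pt]
            summ = jclassify.summarize_by_category(rows, cmap, pt)
            df = jclassify.summaries_to_frame(summ)
            tot_drugs, tot_reports = jclassify.category_total(summ)
            df.loc[len(df)] = ["Total", tot_drugs, "", tot_reports]
            slug = pt.lower().replace(" ", "_")
            df.to_csv(out / f"category_{slug}.tsv", sep="\t", index=False,
                      lineterminator="\n")
        kept_for_overlap = partition.kept
    else:
        kept_for_overlap = list(flagged)

    multi = jclassify.find_multi_pt_drugs(kept_for_overlap)
    pd.DataFrame(
        {
            "drug_name": sorted(multi),
            "pts": ["; ".join(sorted(multi[d])) for d in sorted(multi)],
        }
    ).to_csv(out / "multi_pt_drugs.tsv", sep="\t", index=False, lineterminator="\n")

    if config.annotation:
        ann = InsertAnnotation.from_csv(config.annotation)
        rows = []
        for pt in sorted({s.pt_name for s in kept_for_overlap}):
            fam = pt_family(pt)
            if fam is None:
                continue
            status = jclassify.annotate_insert_status(
                [s for s in kept_for_overlap if s.pt_name == pt], ann, fam
            )
            rows.append(
                {
                    "pt_name": pt,
                    "family": fam,
                    "n_listed": status.n_listed,
                    "n_unlisted": status.n_unlisted,
                    "n_unreviewed": len(status.unreviewed),
                    "unreviewed": "; ".join(status.unreviewed),
                }
            )
        pd.DataFrame(
            rows,
            columns=["pt_name", "family", "n_listed", "n_unlisted",
                     "n_unreviewed", "unreviewed"],
        ).to_csv(out / "insert_status.tsv", sep="\t", index=False,
                 lineterminator="\n")
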