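"""Therapeutic-category classification of signal-detected drugs.

Signal drugs are grouped by the Japanese commodity-classification
therapeutic categories (3-digit codes; codes beginning "42" are
antineoplastic agents and are excluded so that appetite/taste events
attributable to cancer itself do not masquerade as drug signals).
The category map and the package-insert annotation table are user
inputs; the official classification list is not redistributed here.
Drugs missing from either table are surfaced explicitly — never
silently dropped or defaulted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .io import normalize_name
from .stats import SignalResult

ANTINEOPLASTIC_PREFIX = "42"


@dataclass(frozen=True)
class CategoryEntry:
    category_code: str
    category_label: str


class CategoryMap:
    """drug_name → (therapeutic category code, label), misses reported."""

    def __init__(self, entries: Mapping[str, tuple[str, str]]):
        self._entries = {
            normalize_name(k): CategoryEntry(str(code), label)
            for k, (code, label) in entries.items()
        }
        for name, e in self._entries.items():
            if not e.category_code or not e.category_code.isdigit():
                raise ValueError(
                    f"category code for {name!r} must be digits, got {e.category_code!r}"
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CategoryMap":
        df = pd.read_csv(path, dtype=str)
        for col in ("drug_name", "category_code", "category_label"):
            if col not in df.columns:
                raise ValueError(f"category map missing column {col!r}")
        return cls(
            {
                r.drug_name: (r.category_code, r.category_label)
                for r in df.itertuples()
            }
        )

    def lookup(self, drug_name: str) -> CategoryEntry | None:
        return self._entries.get(normalize_name(drug_name))

    def __len__(self) -> int:
        return len(self._entries)


class InsertAnnotation:
    """drug_name → package-insert listing flags; unreviewed drugs surfaced.

    Each reviewed drug carries two explicit booleans: whether decreased
    appetite and whether taste-related reactions are described in its
    package insert.  Absence from the table means "not reviewed", which
    is reported as such, never coerced to False.
    """

    def __init__(self, flags: Mapping[str, tuple[bool, bool]]):
        self._flags = {
            normalize_name(k): (bool(a), bool(t)) for k, (a, t) in flags.items()
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "InsertAnnotation":
        df = pd.read_csv(path, dtype=str)
        for col in ("drug_name", "appetite_listed", "taste_listed"):
            if col not in df.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        truthy = {"true": True, "false": False, "1": True, "0": False}

        def parse(v: str, row: int) -> bool:
            key = str(v).strip().lower()
            if key not in truthy:
                raise ValueError(f"annotation row {row}: flag must be true/false, got {v!r}")
            return truthy[key]

        return cls(
            {
                r.drug_name: (
                    parse(r.appetite_listed, i + 1),
                    parse(r.taste_listed, i + 1),
                )
                for i, r in enumerate(df.itertuples())
            }
        )

    def lookup(self, drug_name: str) -> tuple[bool, bool] | None:
        return self._flags.get(normalize_name(drug_name))


@dataclass(frozen=True)
class ExclusionResult:
    """Partition of signals by the antineoplastic prefix rule."""

    kept: list[SignalResult]
    excluded: list[SignalResult]
    unresolved: list[SignalResult]


def exclude_antineoplastics(
    signals: Sequence[SignalResult],
    category_map: CategoryMap,
    prefix: str = ANTINEOPLASTIC_PREFIX,
) -> ExclusionResult:
    """Partition signals into kept / excluded / unresolved.

    A drug whose category code starts with the antineoplastic prefix is
    excluded; a drug absent from the map is routed to the unresolved
    review list rather than dropped.  The three lists partition the
    input exactly.
    """
    kept, excluded, unresolved = [], [], []
    for s in signals:
        entry = category_map.lookup(s.drug_name)
        if entry is None:
            unresolved.append(s)
        elif entry.category_code.startswith(prefix):
            excluded.append(s)
        else:
            kept.append(s)
    return ExclusionResult(kept, excluded, unresolved)


@dataclass(frozen=True)
class CategorySummary:
    category_label: str
    n_drugs: int
    drug_names: tuple[str, ...]
    total_reports: int  # Σ a over the category's signal drugs for this PT


def summarize_by_category(
    signals: Sequence[SignalResult],
    category_map: CategoryMap,
    pt_name: str,
) -> list[CategorySummary]:
    """Category rows for one PT's signal drugs (post-exclusion).

    One row per category present, ordered by descending drug count,
    then descending total reports, then label.  Drug counts across rows
    sum to the number of input signals; drugs missing from the map
    raise, since exclusion should have routed them already.
    """
    wanted = normalize_name(pt_name)
    by_cat: dict[str, list[SignalResult]] = {}
    for s in signals:
        if normalize_name(s.pt_name) != wanted:
            raise ValueError(
                f"signal for {s.pt_name!r} passed to category summary for {pt_name!r}"
            )
        entry = category_map.lookup(s.drug_name)
        if entry is None:
            raise ValueError(f"drug {s.drug_name!r} unresolved in category map")
        by_cat.setdefault(entry.category_label, []).append(s)
    rows = [
        CategorySummary(
            category_label=label,
            n_drugs=len(group),
            drug_names=tuple(sorted({s.drug_name for s in group})),
            total_reports=sum(s.table.a for s in group),
        )
        for label, group in by_cat.items()
    ]
    rows.sort(key=lambda r: (-r.n_drugs, -r.total_reports, r.category_label))
    return rows


def category_total(summaries: Sequence[CategorySummary]) -> tuple[int, int]:
    """The (Σ drugs, Σ reports) total row of a category table."""
    return (sum(s.n_drugs for s in summaries), sum(s.total_reports for s in summaries))


def find_multi_pt_drugs(
    all_signals: Sequence[SignalResult],
) -> dict[str, set[str]]:
    """Drugs flagged as signals for two or more distinct PTs.

    Only true signals (both criteria met) count; the result is
    independent of PT processing order.
    """
    pts_by_drug: dict[str, set[str]] = {}
    for s in all_signals:
        if s.signal:
            pts_by_drug.setdefault(s.drug_name, set()).add(s.pt_name)
    return {d: pts for d, pts in pts_by_drug.items() if len(pts) >= 2}


@dataclass(frozen=True)
class InsertStatus:
    n_listed: int
    n_unlisted: int
    unreviewed: tuple[str, ...]


def annotate_insert_status(
    signals: Sequence[SignalResult],
    annotation: InsertAnnotation,
    pt_family: Literal["appetite", "taste"],
) -> InsertStatus:
    """Cross-tabulate signal drugs against package-insert descriptions.

    Appetite-family PTs consult the appetite flag, taste-family PTs the
    taste flag.  ``n_listed + n_unlisted + len(unreviewed)`` equals the
    number of distinct signal drugs passed in.
    """
    drugs = sorted({s.drug_name for s in signals})
    listed = unlisted = 0
    unreviewed: list[str] = []
    idx = 0 if pt_family == "appetite" else 1
    for drug in drugs:
        flags = annotation.lookup(drug)
        if flags is None:
            unreviewed.append(drug)
        elif flags[idx]:
            listed += 1
        else:
            unlisted += 1
    return InsertStatus(listed, unlisted, tuple(unreviewed))


def summaries_to_frame(summaries: Iterable[CategorySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category_label": s.category_label,
                "n_drugs": s.n_drugs,
                "drug_names": "; ".join(s.drug_names),
                "total_reports": s.total_reports,
            }
            for s in summaries
        ],
        columns=["category_label", "n_drugs", "drug_names", "total_reports"],
    )
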