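"""Preferred-Term query sets and restriction of the pair universe.

Target adverse events are named by MedDRA Preferred Terms (PTs), each
with an 8-digit code.  The packaged default query set holds the seven
nutrition-related PTs analyzed by the pipeline — three describing
appetite loss (Appetite disorder, Decreased appetite, Abnormal loss of
weight) and four describing taste disturbance (Ageusia, Dysgeusia,
Hypogeusia, Taste disorder).  PT selection is deliberately flat: no
hierarchy (SOC/HLGT/HLT) expansion and no SMQs, to keep signal
specificity under the user's control.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .exceptions import QueryError
from .io import PairUniverse, normalize_name

_PT_FAMILY = {
    "appetite disorder": "appetite",
    "decreased appetite": "appetite",
    "abnormal loss of weight": "appetite",
    "ageusia": "taste",
    "dysgeusia": "taste",
    "hypogeusia": "taste",
    "taste disorder": "taste",
}


@dataclass(frozen=True)
class PTQuery:
    """One target Preferred Term: display name plus 8-digit MedDRA code."""

    pt_name: str
    pt_code: str

    def __post_init__(self) -> None:
        if not (len(self.pt_code) == 8 and self.pt_code.isdigit()):
            raise QueryError(f"pt_code must be 8 digits, got {self.pt_code!r}")
        if not self.pt_name.strip():
            raise QueryError("pt_name must be non-empty")

    @property
    def norm_name(self) -> str:
        return normalize_name(self.pt_name)


@dataclass(frozen=True)
class PTSummary:
    """Report and drug counts for one queried PT."""

    pt_name: str
    n_reports: int
    n_drugs: int


def _validate_queries(queries: Sequence[PTQuery]) -> None:
    if not queries:
        raise QueryError("query set is empty")
    codes = [q.pt_code for q in queries]
    if len(set(codes)) != len(codes):
        raise QueryError("duplicate pt_code in query set")
    names = [q.norm_name for q in queries]
    if len(set(names)) != len(names):
        raise QueryError("duplicate pt_name in query set")


def default_pt_set() -> list[PTQuery]:
    """The packaged seven nutrition-related PT queries."""
    with resources.files("jadersig.data").joinpath("default_pts.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, dtype=str)
    return [PTQuery(r.pt_name, r.pt_code) for r in df.itertuples()]


def load_pt_queries(path: str | Path) -> list[PTQuery]:
    """Load a two-column (pt_name, pt_code) CSV of PT queries."""
    df = pd.read_csv(path, dtype=str)
    for col in ("pt_name", "pt_code"):
        if col not in df.columns:
            raise QueryError(f"PT query file missing column {col!r}")
    queries = [PTQuery(r.pt_name, r.pt_code) for r in df.itertuples()]
    _validate_queries(queries)
    return queries


def pt_family(pt_name: str) -> Literal["appetite", "taste"] | None:
    """Classify a default-set PT as appetite- or taste-related."""
    return _PT_FAMILY.get(normalize_name(pt_name))


def _match_mask(
    pairs: pd.DataFrame,
    query: PTQuery,
    match_on: Literal["code", "name", "either"],
) -> pd.Series:
    by_code = pairs["pt_code"].astype(object).eq(query.pt_code)
    by_name = pairs["pt_name"].eq(query.norm_name)
    if match_on == "code":
        return by_code
    if match_on == "name":
        return by_name
    return by_code | by_name


def extract_target_pairs(
    universe: PairUniverse,
    queries: Sequence[PTQuery],
    match_on: Literal["code", "name", "either"] = "either",
) -> PairUniverse:
    """Restrict the pair universe to pairs whose PT matches a query.

    The full universe must be retained by the caller: it provides the
    contingency margins (cells b and d) for signal detection.  Matching
    is idempotent and a pair matches at most one query in the default
    (disjoint-PT) set.
    """
    _validate_queries(list(queries))
    mask = pd.Series(False, index=universe.pairs.index)
    for q in queries:
        mask |= _match_mask(universe.pairs, q, match_on)
    return PairUniverse(universe.pairs[mask].reset_index(drop=True))


def summarize_pt_counts(
    universe: PairUniverse,
    queries: Sequence[PTQuery],
    match_on: Literal["code", "name", "either"] = "either",
) -> list[PTSummary]:
    """Per-query report and distinct-drug counts, in query order.

    ``n_reports`` is the number of (case, drug, PT) pairs naming the
    PT — the 2×2 cell a summed over all drugs — and ``n_drugs`` the
    number of distinct suspected drugs among those pairs.
    """
    _validate_queries(list(queries))
    out = []
    for q in queries:
        sub = universe.pairs[_match_mask(universe.pairs, q, match_on)]
        out.append(PTSummary(q.pt_name, len(sub), sub["drug_name"].nunique()))
    return out


def summaries_to_frame(summaries: Iterable[PTSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
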