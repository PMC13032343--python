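"""Reading, deduplicating and linking spontaneous-report tables.

The analysis consumes two CSV tables linked by a case identification
number: a drug table (one row per drug per report, carrying a role —
suspected, concomitant or interacting) and a reaction table (one row per
adverse event per report, named by a MedDRA Preferred Term).  A case may
be reported several times; the report iteration is a version number and
only one version per case enters the analysis.

The canonical in-memory container is a :class:`pandas.DataFrame` with
fixed column names (:data:`DRUG_FIELDS` / :data:`REAC_FIELDS`); light
dataclasses are provided for row-level work.  The analysis unit produced
here is the *drug–event pair*: one unique (case, suspected drug, PT)
triple — when a report lists several suspected drugs, each drug counts
as a separate adverse-reaction report, and the same drug/PT combination
is counted at most once per case.
"""

from __future__ import annotations

import csv
import io as _io
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .dialects import ROLES, TableDialect, get_dialect
from .exceptions import (
    EncodingDetectionError,
    RecordValidationError,
    RoleValueError,
    SchemaError,
)

DRUG_FIELDS = ("case_id", "version", "drug_seq", "role", "drug_name")
REAC_FIELDS = ("case_id", "version", "pt_name", "pt_code")
PAIR_FIELDS = ("case_id", "drug_name", "pt_name", "pt_code")

_PT_CODE_RE = re.compile(r"^[0-9]{8}$")


@dataclass(frozen=True)
class DrugRecord:
    case_id: str
    version: int
    drug_seq: int
    role: str
    drug_name: str


@dataclass(frozen=True)
class EventRecord:
    case_id: str
    version: int
    pt_name: str
    pt_code: str | None = None


@dataclass(frozen=True)
class DrugEventPair:
    case_id: str
    drug_name: str
    pt_name: str
    pt_code: str | None = None


def normalize_name(name: str) -> str:
    """Normalize a drug or PT name: NFKC fold, trim, case fold.

    Exact string identity after this normalization is the package's
    notion of drug identity (spontaneous-report dumps do not separate
    brand and generic names, so no further resolution is attempted).
    """
    return unicodedata.normalize("NFKC", name).strip().casefold()


@dataclass
class PairUniverse:
    """The full set of unique (case, suspected drug, PT) triples.

    ``n_total`` is the grand total N of every 2×2 contingency margin
    built downstream.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PAIR_FIELDS) - set(self.pairs.columns)
        if missing:
            raise ValueError(f"pair frame missing columns {sorted(missing)}")
        self.pairs = self.pairs.loc[:, list(PAIR_FIELDS)].reset_index(drop=True)

    @property
    def n_total(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairUniverse":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        df["pt_code"] = df["pt_code"].replace("", None)
        return cls(df)


def _read_text(path: str | Path, encodings: Iterable[str]) -> str:
    raw = Path(path).read_bytes()
    tried = []
    for enc in encodings:
        tried.append(enc)
        try:
            return raw.decode(enc)
        except UnicodeDecodeError:
            continue
    raise EncodingDetectionError(str(path), tried)


def read_table(
    path: str | Path,
    table_kind: Literal["drug", "reac"],
    dialect: str | TableDialect = "japanese",
) -> pd.DataFrame:
    """Read one JADER-style CSV table into the canonical schema.

    Returns a DataFrame with :data:`DRUG_FIELDS` or :data:`REAC_FIELDS`
    columns, row order preserved.  Role strings are mapped through the
    dialect's vocabulary; drug and PT names are normalized with
    :func:`normalize_name`.

    Raises
    ------
    SchemaError
        if a column the dialect maps is absent from the header.
    RoleValueError
        listing every role string (with its 1-based data row number)
        not in the dialect's vocabulary.
    EncodingDetectionError
        if no candidate encoding decodes the file.
    RecordValidationError
        for empty names or malformed (non-8-digit) PT codes.
    """
    dialect = get_dialect(dialect)
    text = _read_text(path, dialect.encodings)
    raw = pd.read_csv(_io.StringIO(text), dtype=str, keep_default_na=False)

    colmap = dialect.drug_columns if table_kind == "drug" else dialect.reac_columns
    out = pd.DataFrame(index=raw.index)
    for canonical, physical in colmap.items():
        if physical not in raw.columns:
            if canonical == "pt_code":  # optional in the reaction table
                continue
            raise SchemaError(physical, str(path))
        out[canonical] = raw[physical]

    if len(out) == 0:
        fields = DRUG_FIELDS if table_kind == "drug" else REAC_FIELDS
        return pd.DataFrame(
            {
                f: pd.Series(dtype="int64" if f in ("version", "drug_seq") else object)
                for f in fields
            }
        )

    out["case_id"] = out["case_id"].astype(str)
    out["version"] = pd.to_numeric(out["version"], errors="raise").astype(int)

    if table_kind == "drug":
        out["drug_seq"] = pd.to_numeric(out["drug_seq"], errors="raise").astype(int)
        bad = [
            (v, i + 1)
            for i, v in enumerate(out["role"])
            if v not in dialect.role_vocabulary
        ]
        if bad:
            raise RoleValueError(bad)
        out["role"] = out["role"].map(dialect.role_vocabulary)
        out["drug_name"] = out["drug_name"].map(normalize_name)
        if (out["drug_name"] == "").any():
            rows = (out.index[out["drug_name"] == ""] + 1).tolist()
            raise RecordValidationError(f"empty drug_name in data rows {rows}")
        return out.loc[:, list(DRUG_FIELDS)]

    out["pt_name"] = out["pt_name"].map(normalize_name)
    if (out["pt_name"] == "").any():
        rows = (out.index[out["pt_name"] == ""] + 1).tolist()
        raise RecordValidationError(f"empty pt_name in data rows {rows}")
    if "pt_code" in out.columns:
        codes = out["pt_code"].str.strip().replace("", None)
        bad_mask = codes.notna() & ~codes.str.fullmatch(_PT_CODE_RE.pattern).fillna(False)
        if bad_mask.any():
            rows = (out.index[bad_mask] + 1).tolist()
            raise RecordValidationError(
                f"pt_code must be 8 digits; offending data rows {rows}"
            )
        out["pt_code"] = codes
    else:
        out["pt_code"] = None
    return out.loc[:, list(REAC_FIELDS)]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    table_kind: Literal["drug", "reac"],
    dialect: str | TableDialect = "japanese",
) -> None:
    """Write a canonical-schema table back to CSV under a dialect.

    Inverse of :func:`read_table` for already-normalized content:
    canonical column names map back to the dialect's physical headers
    and canonical roles back to the dialect's first physical label.
    """
    dialect = get_dialect(dialect)
    colmap = dialect.drug_columns if table_kind == "drug" else dialect.reac_columns
    out = pd.DataFrame(index=df.index)
    inv_roles = dialect.inverse_role_vocabulary
    for canonical, physical in colmap.items():
        if canonical not in df.columns:
            continue
        col = df[canonical]
        if canonical == "role":
            col = col.map(inv_roles)
        out[physical] = col
    out.to_csv(
        path,
        index=False,
        encoding=dialect.encodings[0],
        quoting=csv.QUOTE_MINIMAL,
        lineterminator="\n",
    )


def deduplicate_cases(
    records: pd.DataFrame,
    strategy: Literal["latest_version", "first_seen"] = "latest_version",
) -> pd.DataFrame:
    """Keep exactly one report version per case.

    ``latest_version`` retains each case's maximum version number (the
    convention for spontaneous-report dumps, where later report
    iterations supersede earlier ones); ``first_seen`` retains the
    version of the case's first row in file order.  All rows of the
    retained version are kept, in their original order.
    """
    if len(records) == 0:
        return records.copy()
    if strategy == "latest_version":
        chosen = records.groupby("case_id")["version"].transform("max")
    elif strategy == "first_seen":
        first = records.drop_duplicates("case_id").set_index("case_id")["version"]
        chosen = records["case_id"].map(first)
    else:
        raise ValueError(f"unknown dedup strategy {strategy!r}")
    return records[records["version"] == chosen].copy()


def filter_suspected(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only suspected-drug records (order preserved).

    Concomitant and interacting drugs are excluded so that every
    analyzed pair carries the reporter's judgement of association.
    """
    if len(records) == 0:
        return records.copy()
    return records[records["role"] == "suspected"].copy()


def link_drug_event(
    drugs: pd.DataFrame,
    events: pd.DataFrame,
    unit: Literal["triple", "row"] = "triple",
) -> PairUniverse:
    """Join drug and reaction records by case id into the pair universe.

    Under the default ``triple`` unit, pairs within a case are the
    product of its distinct drug names and distinct PTs, collapsed to
    unique (case_id, drug_name, pt_name).  The ``row`` unit skips the
    collapse and joins raw rows, so a drug listed under several
    ``drug_seq`` entries (or a PT reported twice) is counted each time;
    it exists because public headline counts from reporting databases
    do not always state which unit they used.  Cases present in only
    one table contribute nothing.  Both inputs should already be
    deduplicated to one version per case.
    """
    if len(drugs) == 0 or len(events) == 0:
        return PairUniverse(
            pd.DataFrame({f: pd.Series(dtype=object) for f in PAIR_FIELDS})
        )
    d = drugs.loc[:, ["case_id", "drug_name"]]
    e = events.loc[:, ["case_id", "pt_name", "pt_code"]]
    if unit == "triple":
        d = d.drop_duplicates()
        e = e.drop_duplicates(subset=["case_id", "pt_name"])
    pairs = d.merge(e, on="case_id", how="inner")
    if unit == "triple":
        pairs = pairs.drop_duplicates(subset=["case_id", "drug_name", "pt_name"])
    return PairUniverse(pairs.reset_index(drop=True))


def frame_to_records(df: pd.DataFrame, table_kind: Literal["drug", "reac"]):
    """Convert a canonical frame to a list of typed records."""
    cls = DrugRecord if table_kind == "drug" else EventRecord
    fields = DRUG_FIELDS if table_kind == "drug" else REAC_FIELDS
    return [cls(**{f: row[f] for f in fields}) for row in df.to_dict("records")]
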