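"""Table dialects: physical column names, role vocabulary and encodings.

Spontaneous-report dumps differ only in surface details — header language,
role labels, character encoding — so all of those live here and none are
hard-coded in analysis logic.  Two dialects ship with the package:

``japanese``
    The PMDA JADER export: CP932-encoded CSVs whose drug table carries
    識別番号 (case id), 報告回数 (report iteration), 医薬品連番 (drug
    sequence), 医薬品の関与 (role: 被疑薬/併用薬/相互作用) and
    医薬品（一般名） (ingredient name), and whose reaction table carries
    the adverse-event PT name under 有害事象.

``ascii``
    A plain UTF-8 dialect with English headers, used by the synthetic
    generator and the test fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: canonical role values used throughout the package
ROLES = ("suspected", "concomitant", "interacting")


@dataclass(frozen=True)
class TableDialect:
    """Mapping from physical CSV columns to the canonical schema.

    Parameters
    ----------
    name
        Identifier for the dialect.
    drug_columns
        Maps canonical drug-table fields (``case_id``, ``version``,
        ``drug_seq``, ``role``, ``drug_name``) to physical header names.
    reac_columns
        Maps canonical reaction-table fields (``case_id``, ``version``,
        ``pt_name`` and optionally ``pt_code``) to physical header names.
    role_vocabulary
        Maps the file's role strings to the canonical
        ``suspected`` / ``concomitant`` / ``interacting``.
    encodings
        Candidate encodings tried in order when reading.
    """

    name: str
    drug_columns: dict[str, str]
    reac_columns: dict[str, str]
    role_vocabulary: dict[str, str]
    encodings: tuple[str, ...] = ("utf-8",)

    def __post_init__(self) -> None:
        for req in ("case_id", "version", "drug_seq", "role", "drug_name"):
            if req not in self.drug_columns:
                raise ValueError(f"dialect {self.name!r}: drug_columns missing {req!r}")
        for req in ("case_id", "version", "pt_name"):
            if req not in self.reac_columns:
                raise ValueError(f"dialect {self.name!r}: reac_columns missing {req!r}")
        bad = set(self.role_vocabulary.values()) - set(ROLES)
        if bad:
            raise ValueError(f"dialect {self.name!r}: unknown canonical roles {sorted(bad)}")

    @property
    def inverse_role_vocabulary(self) -> dict[str, str]:
        """Canonical role -> first physical label (for writing)."""
        inv: dict[str, str] = {}
        for physical, canonical in self.role_vocabulary.items():
            inv.setdefault(canonical, physical)
        return inv

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["encodings"] = list(self.encodings)
        Path(path).write_text(yaml.safe_dump(d, allow_unicode=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableDialect":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        d["encodings"] = tuple(d.get("encodings", ("utf-8",)))
        return cls(**d)


JAPANESE = TableDialect(
    name="japanese",
    drug_columns={
        "case_id": "識別番号",
        "version": "報告回数",
        "drug_seq": "医薬品連番",
        "role": "医薬品の関与",
        "drug_name": "医薬品（一般名）",
    },
    reac_columns={
        "case_id": "識別番号",
        "version": "報告回数",
        "pt_name": "有害事象",
    },
    role_vocabulary={"被疑薬": "suspected", "併用薬": "concomitant", "相互作用": "interacting"},
    encodings=("cp932", "utf-8"),
)

ASCII = TableDialect(
    name="ascii",
    drug_columns={
        "case_id": "case_id",
        "version": "version",
        "drug_seq": "drug_seq",
        "role": "role",
        "drug_name": "drug_name",
    },
    reac_columns={
        "case_id": "case_id",
        "version": "version",
        "pt_name": "pt_name",
        "pt_code": "pt_code",
    },
    role_vocabulary={"suspected": "suspected", "concomitant": "concomitant", "interacting": "interacting"},
    encodings=("utf-8",),
)

BUILTIN_DIALECTS: dict[str, TableDialect] = {"japanese": JAPANESE, "ascii": ASCII}


def get_dialect(name_or_path: str | TableDialect) -> TableDialect:
    """Resolve a dialect by builtin name, YAML path, or pass-through."""
    if isinstance(name_or_path, TableDialect):
        return name_or_path
    if name_or_path in BUILTIN_DIALECTS:
        return BUILTIN_DIALECTS[name_or_path]
    p = Path(name_or_path)
    if p.exists():
        return TableDialect.from_yaml(p)
    raise KeyError(
        f"unknown dialect {name_or_path!r}; builtin dialects: {sorted(BUILTIN_DIALECTS)}"
    )
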