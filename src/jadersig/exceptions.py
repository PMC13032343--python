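"""Exception hierarchy for jadersig."""


class JadersigError(Exception):
    """Base class for all package errors."""


class SchemaError(JadersigError):
    """A required column named by the dialect is missing from the file."""

    def __init__(self, column: str, path: str | None = None):
        self.column = column
        self.path = path
        where = f" in {path}" if path else ""
        super().__init__(f"required column {column!r} not found{where}")


class RoleValueError(JadersigError):
    """A role cell holds a string absent from the dialect's role vocabulary."""

    def __init__(self, values_with_rows: list[tuple[str, int]]):
        self.values_with_rows = values_with_rows
        shown = ", ".join(f"{v!r} (row {r})" for v, r in values_with_rows[:10])
        more = "" if len(values_with_rows) <= 10 else f" and {len(values_with_rows) - 10} more"
        super().__init__(f"unmappable role value(s): {shown}{more}")


class EncodingDetectionError(JadersigError):
    """None of the dialect's candidate encodings could decode the file."""

    def __init__(self, path: str, tried: list[str]):
        self.path = path
        self.tried = tried
        super().__init__(
            f"could not decode {path} with any of the dialect encodings {tried}; "
            f"pass a dialect with the correct encoding (e.g. cp932 for PMDA exports, "
            f"utf-8 for exported/synthetic tables)"
        )


class QueryError(JadersigError):
    """Invalid PT query set (e.g. empty, duplicate codes)."""


class RecordValidationError(JadersigError):
    """A loaded row violates a record invariant."""
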