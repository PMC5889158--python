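"""Typed exceptions raised by table validation and code-list loading."""


class RheumClaimsError(Exception):
    """Base class for all package errors."""


class SchemaError(RheumClaimsError):
    """A table file is missing a required column or has a malformed header."""


class RowValidationError(RheumClaimsError):
    """A data row violates a type invariant.

    Carries enough context (table, row number) to locate the offending line
    in the source file; row numbers are 1-based data-row indices, i.e. the
    header is row 0.
    """

    def __init__(self, table: str, row: int, message: str):
        self.table = table
        self.row = row
        super().__init__(f"{table} row {row}: {message}")


class CodeListError(RheumClaimsError):
    """A code-list file is malformed (duplicate name, empty list, bad rule)."""


class ConfigError(RheumClaimsError):
    """A study-configuration value is out of range or unparseable."""
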