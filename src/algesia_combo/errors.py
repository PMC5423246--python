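"""Typed exceptions and warnings used across the package.

Validation errors (bad configs, malformed datasets) are distinguished from
runtime/analysis errors so that the command line tool can map them to
distinct exit codes.
"""


class AlgesiaError(Exception):
    """Base class for all package errors."""


class ValidationError(AlgesiaError, ValueError):
    """Invalid user input: configuration fields, dataset contents, arm maps."""


class ConfigError(ValidationError):
    """A simulation or run configuration violates an invariant.

    The message always names the offending field.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DatasetError(ValidationError):
    """A behavioral dataset violates the tabular schema.

    ``rows`` carries 1-based CSV row numbers (header excluded) where known.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = rows or []
        if self.rows:
            message = f"{message} (rows {', '.join(map(str, self.rows))})"
        super().__init__(message)


class MissingColumnError(DatasetError):
    pass


class DuplicateRecordError(DatasetError):
    pass


class OutOfRangeError(DatasetError):
    pass


class UnknownAssayError(DatasetError):
    pass


class AnalysisError(AlgesiaError):
    """A computation cannot proceed (degenerate denominator, too few points)."""


class ExclusionWarning(UserWarning):
    """An animal was excluded or flagged (too few observations, missing days)."""
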