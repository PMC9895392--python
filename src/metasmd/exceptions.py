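"""Exception hierarchy shared across the package."""


class MetasmdError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MetasmdError):
    """A required column is missing or the table layout is unusable."""


class RowParseError(MetasmdError):
    """A data row could not be parsed; carries the 1-based row number."""

    def __init__(self, row: int, message: str) -> None:
        self.row = row
        super().__init__(f"row {row}: {message}")


class ValidationError(MetasmdError):
    """A value violates a domain invariant."""


class DegenerateStudyError(MetasmdError):
    """A study has zero pooled within-group SD and no defined SMD."""


class InsufficientStudiesError(MetasmdError):
    """Fewer studies than the operation requires."""
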