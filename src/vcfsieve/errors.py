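"""Exception hierarchy.

Every error that originates from user input carries enough context (line
number, field name, sample id) to be actionable from a shell.
"""

from __future__ import annotations


class VCFSieveError(Exception):
    """Base class for all package errors."""


class VCFParseError(VCFSieveError):
    """A VCF header or body line could not be parsed.

    Parameters
    ----------
    message:
        Human-readable description of the defect.
    line_number:
        1-based line number in the source file, when known.
    line_text:
        The offending line, when known.
    """

    def __init__(self, message: str, line_number: int | None = None,
                 line_text: str | None = None):
        self.line_number = line_number
        self.line_text = line_text
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class GenotypeError(VCFSieveError):
    """A GT or AD field value is malformed."""


class UnknownFieldError(VCFSieveError):
    """A field path does not exist in the dataset's catalog."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"unknown field: {field!r}")


class FilterSpecError(VCFSieveError):
    """A filter's kind, operator and value are inconsistent."""


class GroupError(VCFSieveError):
    """A sample group references samples absent from the dataset."""


class RangeError(VCFSieveError):
    """A BED line or pasted range token is malformed."""


class StrategyError(VCFSieveError):
    """A saved filter strategy cannot be loaded or resolved."""


class TrioError(VCFSieveError):
    """Trio sample ids cannot be resolved against the dataset."""


class FixtureError(VCFSieveError):
    """A synthetic-data request is internally inconsistent."""
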