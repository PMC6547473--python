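"""Error taxonomy shared across the language frontend and the pipeline runtime.

Every user-facing failure is one of these exceptions; the CLI maps the
classes onto its exit codes (parse/type errors, pre-flight failures and
runtime stage errors are distinguishable by construction, not by message
grepping).
"""

from __future__ import annotations


class NGLError(Exception):
    """Base class for all errors raised by this package."""


class SourceError(NGLError):
    """An error anchored at a position in a script source file."""

    def __init__(self, message: str, line: int | None = None, col: int | None = None):
        self.message = message
        self.line = line
        self.col = col
        super().__init__(str(self))

    def __str__(self) -> str:  # pragma: no cover - formatting only
        if self.line is None:
            return self.message
        if self.col is None:
            return f"line {self.line}: {self.message}"
        return f"line {self.line}, column {self.col}: {self.message}"


class LexicalError(SourceError):
    """Unrecognized character or malformed token."""


class ParseError(SourceError):
    """Syntactically invalid script (includes a missing version declaration)."""


class TypeCheckError(NGLError):
    """One or more static errors found before execution.

    ``findings`` is the full list of (message, line, col) triples; all
    inconsistencies found in one pass are reported together.
    """

    def __init__(self, findings):
        self.findings = list(findings)
        msgs = "; ".join(
            (f"line {ln}: {msg}" if ln is not None else msg) for msg, ln, _ in self.findings
        )
        super().__init__(msgs or "type error")


class PreflightError(NGLError):
    """Raised by the CLI when pre-flight validation returns findings."""

    def __init__(self, findings):
        self.findings = list(findings)
        super().__init__("; ".join(str(f) for f in self.findings) or "preflight failure")


class StageError(NGLError):
    """A pipeline stage failed during interpretation."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


class FastqFormatError(NGLError):
    """Malformed FASTQ input; carries the 1-based record number when known."""

    def __init__(self, message: str, record: int | None = None):
        self.record = record
        if record is not None:
            message = f"record {record}: {message}"
        super().__init__(message)


class SamFormatError(NGLError):
    """Malformed SAM input."""


class RegistryError(NGLError):
    """Unknown reference name or unusable registry entry."""
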