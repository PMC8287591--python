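"""Exception hierarchy.

All package errors derive from :class:`CibError` so callers (and the CLI)
can distinguish domain failures (exit code 1) from usage errors (exit 2).
"""

from __future__ import annotations


class CibError(Exception):
    """Base class for all cibscen errors."""


class ValidationError(CibError):
    """An object violates a structural invariant (unknown factor, bad state,
    incomplete scenario, mismatched factor spaces, ...)."""


class ConfigurationError(CibError):
    """An option value is not recognised (e.g. an invalid consistency mode)."""


class ScoreRangeError(ValidationError):
    """A judgment score lies outside the permitted integer range."""


class CatalogError(CibError):
    """A relationship shape is not present in the encoding table."""

    def __init__(self, shape: str, known: tuple[str, ...]):
        self.shape = shape
        self.known = tuple(known)
        super().__init__(
            f"unknown relationship shape {shape!r}; known shapes: {', '.join(self.known)}"
        )


class DuplicateJudgmentError(ValidationError):
    """Two responses (or matrix rows) address the same ordered factor pair."""


class SizeGuardError(CibError):
    """Exhaustive enumeration refused because the state space is too large."""

    def __init__(self, count: int, limit: int):
        self.count = count
        self.limit = limit
        super().__init__(
            f"refusing to enumerate {count} candidate scenarios (guard limit {limit})"
        )


class EmptyScenarioSetError(CibError):
    """A summary metric was requested for an empty scenario set.

    Raised instead of returning 0 so that no-solution cases are never
    silently folded into legitimate percentages.
    """


class InfeasibleMarginError(CibError):
    """A planted consistency margin cannot be realised on the +/-2 scale."""


class ParseError(CibError):
    """A file could not be parsed; carries file, line and field context."""

    def __init__(self, path, line: int | None, field: str | None, message: str):
        self.path = str(path)
        self.line = line
        self.field = field
        loc = self.path
        if line is not None:
            loc += f":{line}"
        if field:
            loc += f" (field {field!r})"
        super().__init__(f"{loc}: {message}")
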