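"""Exception hierarchy shared across the package.

Every error a parser or pipeline stage can raise derives from
:class:`CircleMapError`, so callers (notably the CLI) can catch one type
and report a diagnostic with nonzero exit status.
"""


class CircleMapError(Exception):
    """Base class for all package errors."""


class FormatError(CircleMapError):
    """Malformed input text (ragged row, bad field count, empty file).

    Parameters
    ----------
    message:
        Human-readable description.
    line:
        1-based line number in the offending stream, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateKeyError(CircleMapError):
    """A gene symbol, sample id or track name occurs more than once."""


class VocabularyError(CircleMapError):
    """Unknown relation token, entity type or edge type."""


class UnknownNodeError(CircleMapError):
    """An edge references a node that was never declared."""


class ConfigurationError(CircleMapError):
    """Invalid render configuration or color-scale parameters."""


class StateError(CircleMapError):
    """Operation invoked on an object in the wrong state (e.g. unlaid-out scene)."""


class SpecificationError(CircleMapError):
    """Synthetic-generator parameters violate their invariants."""


class KeyResolutionError(CircleMapError, KeyError):
    """A sort key or gene lookup cannot be resolved against the data."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep plain message
        return Exception.__str__(self)
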