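"""Exception hierarchy shared across the package."""


class KsclassError(Exception):
    """Base class for all package errors."""


class EmptyInputError(KsclassError):
    """An operation received an empty stream, sequence or collection."""


class DuplicateIdError(KsclassError):
    """Two records share the same identifier."""


class AlignmentShapeError(KsclassError):
    """Alignment rows are ragged or too few."""


class ParameterError(KsclassError):
    """A parameter is outside its documented range."""


class EmptyModelError(KsclassError):
    """No alignment column qualified as a match state."""


class ProfileParseError(KsclassError):
    """A profile file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnsupportedAlphabetError(KsclassError):
    """Profile alphabet is not amino."""


class SchemaVersionError(KsclassError):
    """Serialized profile has an unknown schema version."""


class ValidationError(KsclassError):
    """A deserialized or constructed object violates its invariants."""


class InputSizeError(KsclassError):
    """Too few rows/points for the requested operation."""


class InsufficientOverlapError(KsclassError):
    """Fewer than two ids are shared between two labelings."""


class UnknownIdError(KsclassError):
    """A referenced identifier is absent."""
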