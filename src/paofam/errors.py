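"""Typed errors raised across the pipeline.

Every reader and operation rejects malformed input with one of these
instead of silently coercing; the CLI maps them onto exit code 2
(user/input error) while anything else becomes exit code 3.
"""


class PaofamError(Exception):
    """Base class for all package errors."""


class FormatError(PaofamError):
    """File content does not follow the documented dialect."""


class DuplicateIdError(FormatError):
    """Two records share the same identifier."""


class AlphabetError(FormatError):
    """A residue outside the amino-acid alphabet (plus X) was found."""


class ValidationError(PaofamError):
    """A value violates a documented invariant (coordinates, ranges...)."""


class AlignmentWidthError(FormatError):
    """Rows of an alignment differ in length."""


class ConsistencyError(PaofamError):
    """Cross-referenced inputs disagree (unknown ids, mismatched lengths)."""


class UndefinedDistanceError(PaofamError):
    """A sequence pair shares no comparable (mutually ungapped) column."""


class MotifParseError(PaofamError):
    """A PROSITE-style pattern string could not be parsed.

    Carries ``offset``, the 0-based byte offset of the offending character.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class ConfigurationError(PaofamError):
    """An operation was invoked with an unusable configuration."""


class MissingReferenceError(PaofamError):
    """The reference sequence is absent from the alignment."""


class EmptyCladeError(PaofamError):
    """A profile was requested for a clade with no members."""


class PlacementError(PaofamError):
    """A motif realization does not fit at the requested position."""


class SerializationError(PaofamError):
    """A tree cannot be written (e.g. non-monotone node heights)."""
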