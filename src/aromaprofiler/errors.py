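"""Exception hierarchy for the aromaprofiler pipeline.

Every stage raises a subclass of :class:`AromaProfilerError` so callers (and
the CLI) can distinguish pipeline failures from programming errors.
"""


class AromaProfilerError(Exception):
    """Base class for all aromaprofiler errors."""


class LibraryParseError(AromaProfilerError):
    """A compound-library or sensory file violates its schema.

    Carries ``row`` (1-based data row, None for file-level problems) and
    ``field`` when the offending cell is known.
    """

    def __init__(self, message, row=None, field=None):
        self.row = row
        self.field = field
        loc = ""
        if row is not None:
            loc += f" [row {row}"
            loc += f", field {field!r}]" if field else "]"
        super().__init__(message + loc)


class ValidationError(AromaProfilerError):
    """A domain value violates an invariant (negative sugar, bad age, ...)."""


class LadderError(AromaProfilerError):
    """An alkane ladder is malformed (non-increasing anchors, gaps)."""


class LadderRangeError(AromaProfilerError):
    """A retention time falls outside the alkane ladder span."""


class MissingInternalStandardError(AromaProfilerError):
    """A peak table has no usable internal-standard peak."""


class UnknownCompoundError(AromaProfilerError):
    """A compound id does not exist in the reference library."""


class UnknownNoteError(AromaProfilerError):
    """An aroma-note token is absent from the descriptor vocabulary."""

    def __init__(self, note, known):
        self.note = note
        self.known = sorted(known)
        super().__init__(
            f"unknown aroma note {note!r}; known notes: {', '.join(self.known)}"
        )
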