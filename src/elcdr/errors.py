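"""Exception hierarchy for the elcdr package."""


class ELCDRError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ELCDRError, ValueError):
    """An input violates a documented precondition (shape, range, count)."""


class DegenerateGeometryError(ELCDRError):
    """Feature-space geometry is degenerate (all clusters collapsed, icD == 0)."""


class AlignmentError(ELCDRError):
    """Tables in one ensemble run disagree on samples or classes."""


class ParseError(ELCDRError):
    """A table file is malformed; the message carries the offending line."""
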