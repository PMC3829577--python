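"""Exception and warning types used across the package."""


class RipplePondError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(RipplePondError, ValueError):
    """A parameter violates an operation's preconditions."""


class InvalidInputError(RipplePondError, ValueError):
    """An input object (image, frame, layout) is malformed."""


class EmptyPatternError(RipplePondError, ValueError):
    """A temporal pattern with no spikes cannot be normalized."""


class UndefinedSimilarityError(RipplePondError, ValueError):
    """Similarity is undefined (zero vector / constant sequence)."""


class NoPeriodError(RipplePondError, ValueError):
    """No dominant period could be found in a similarity curve."""


class UnknownGlyphError(RipplePondError, KeyError):
    """The embedded stroke font has no entry for the requested glyph."""


class ParseError(RipplePondError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class DegenerateImageWarning(UserWarning):
    """A transform shrank the object below one foreground pixel."""
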