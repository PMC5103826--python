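"""Exception hierarchy for gfakit.

All errors raised by the library derive from :class:`GfaError` so callers
can catch a single base class.
"""


class GfaError(Exception):
    """Base class for all gfakit errors."""


# -- record level -----------------------------------------------------------

class ParseError(GfaError):
    """A GFA line could not be parsed."""


class UnknownRecordType(ParseError):
    pass


class MissingRequiredField(ParseError):
    pass


class MalformedTag(ParseError):
    pass


class InvalidTagName(GfaError):
    pass


class TypeMismatch(GfaError):
    """A tag value does not fit its declared datatype."""


# -- graph level ------------------------------------------------------------

class DuplicateName(GfaError):
    pass


class UnknownSegment(GfaError):
    pass


class UnknownName(GfaError):
    pass


class DanglingReferences(GfaError):
    """A non-cascaded deletion would leave records citing a removed name."""


class MissingLength(GfaError):
    """A segment has neither a sequence nor an LN tag."""


class NotIncident(GfaError):
    """A link was queried with a segment end it does not touch."""


# -- coverage / multiplication ---------------------------------------------

class MissingCountTag(GfaError):
    pass


class NonPositiveDenominator(GfaError):
    """Segment shorter than the unit length: |s| - l + 1 < 1."""


class BadFactor(GfaError):
    pass


class DistributionPreconditionViolated(GfaError):
    """Link distribution requires copy number 1 on the copies and on every
    segment reachable from the multiplied segment."""


class MissingCopyNumber(GfaError):
    pass


# -- paths / merging --------------------------------------------------------

class InvalidPath(GfaError):
    pass


class UnsupportedOverlap(GfaError):
    """Junction overlap is not *, 0M or <n>M."""


class MissingSequence(GfaError):
    pass


# -- diff -------------------------------------------------------------------

class ScriptTargetMissing(GfaError):
    """An edit script referenced a record absent from the target graph."""


# -- de Bruijn / fixtures ---------------------------------------------------

class BadAlphabet(GfaError):
    pass


class KTooLarge(GfaError):
    pass


class UnknownFixture(GfaError):
    pass


class UnsatisfiableUniqueness(GfaError):
    """Rejection sampling could not produce sequences satisfying the
    k-mer uniqueness constraints."""
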