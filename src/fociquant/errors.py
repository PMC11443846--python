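"""Exception hierarchy for batch image analysis.

All errors raised by this package derive from :class:`FociQuantError`, so a
caller driving a long batch can catch one type.
"""


class FociQuantError(Exception):
    """Base class for all package errors."""


class DecodeError(FociQuantError):
    """An image file could not be read or is in an unsupported format."""


class InvalidInputError(FociQuantError):
    """Input data violates a structural precondition (shape, emptiness)."""


class InvalidParameterError(FociQuantError):
    """A user-supplied parameter is out of its legal range."""


class BatchMismatchError(FociQuantError):
    """The marker and damage folders contain unequal numbers of images."""


class ShapeMismatchError(FociQuantError):
    """A paired marker/damage image duo has differing pixel dimensions."""


class EmptyBatchError(FociQuantError):
    """A folder holds no readable images, or a histogram has no pixels."""


class InvalidOutputError(FociQuantError):
    """The requested output folder name is reserved or already exists."""


class PlacementError(FociQuantError):
    """The synthetic-scene sampler could not place all objects disjointly."""
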