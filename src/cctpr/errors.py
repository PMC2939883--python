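"""Exception hierarchy for the CC-TPR screen."""


class CctprError(Exception):
    """Base class for all package errors."""


class EmptyInputError(CctprError):
    """An input file or collection contained no usable records."""


class AlphabetError(CctprError):
    """A sequence contains a character outside the accepted amino-acid alphabet."""


class FixtureIntegrityError(CctprError):
    """A packaged or user fixture violates its schema (motif counts, coordinates)."""


class InsufficientDataError(CctprError):
    """Not enough training rows to build a position profile."""


class WindowLengthError(CctprError):
    """A window passed to a fixed-length profile has the wrong length."""


class UndefinedDistanceError(CctprError):
    """A pairwise distance could not be computed (no aligned non-gap columns)."""


class MatrixError(CctprError):
    """A distance matrix is malformed (asymmetric, nonzero diagonal, ...)."""


class RaggedAlignmentError(CctprError):
    """Alignment rows do not all share one length."""


class SyntheticSpecError(CctprError):
    """A synthetic-proteome specification is internally inconsistent."""


class SerializationError(CctprError):
    """An object cannot be written in the requested format."""
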