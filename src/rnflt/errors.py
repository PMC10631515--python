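"""Exception hierarchy for the rnflt package."""


class RNFLTError(Exception):
    """Base class for all rnflt-specific errors."""


class ShapeError(RNFLTError):
    """Grid/mask shapes are inconsistent."""


class GeometryError(RNFLTError):
    """A scan circle or other geometric object does not fit the grid."""


class GenerationError(RNFLTError):
    """A synthetic-data request cannot be satisfied."""


class EligibilityError(RNFLTError):
    """An input does not meet a quality/eligibility precondition."""


class SplitError(RNFLTError):
    """A requested data split is impossible."""


class InsufficientDataError(RNFLTError):
    """Too few observations for the requested fit."""


class UndefinedRegionError(RNFLTError):
    """A metric was requested over an empty region."""


class DegeneratePatternError(RNFLTError):
    """An artifact pattern became empty (e.g. after a transform)."""


class DegenerateBatchError(RNFLTError):
    """A batch is too small for the requested loss."""


class ParseError(RNFLTError):
    """A text grid or table could not be parsed."""
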