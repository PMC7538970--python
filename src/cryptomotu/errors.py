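"""Exception hierarchy for the cryptomotu pipeline."""


class CryptoMotuError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CryptoMotuError):
    """Malformed input file (duplicate ids, bad characters, missing fields)."""


class AlignmentError(CryptoMotuError):
    """Sequences are not aligned / unequal lengths / bad window."""


class EmptyInputError(CryptoMotuError):
    """An operation received an empty dataset."""


class CoverageError(CryptoMotuError):
    """An id universe mismatch: partition, matrix, tree or site table does not
    cover the objects it is applied to."""


class DelimitationError(CryptoMotuError):
    """A delimitation method cannot run (e.g. all distances undefined)."""


class ClockError(CryptoMotuError):
    """Tree is not ultrametric within tolerance, or rate is invalid."""


class TreeShapeError(CryptoMotuError):
    """Tree violates a shape precondition (non-binary node, missing lengths)."""


class GeometryError(CryptoMotuError):
    """Degenerate geometry (too few sites, collinear points)."""


class ConfigError(CryptoMotuError):
    """Invalid configuration values."""


class DegenerateBranchError(CryptoMotuError):
    """A rate class has edges but zero total branch length."""
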