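"""Typed exceptions raised across the pipeline.

Every failure mode a caller may want to catch has its own class; all of
them derive from :class:`MirtempoError` so ``except MirtempoError`` guards
a whole pipeline stage.
"""


class MirtempoError(Exception):
    """Base class for all package-specific errors."""


class MissingFileError(MirtempoError, FileNotFoundError):
    """Input file does not exist."""


class MatrixFormatError(MirtempoError, ValueError):
    """Malformed input matrix; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class RaggedRowError(MatrixFormatError):
    """A row has the wrong number of tab-separated fields."""


class NonNumericCountError(MatrixFormatError):
    """A count cell could not be parsed as a number."""


class NegativeCountError(MatrixFormatError):
    """A count cell is negative."""


class DuplicateFeatureNameError(MatrixFormatError):
    """Two rows share the same feature name."""


class CardinalityError(MirtempoError, ValueError):
    """Time-point count outside [2, 20] or replicate count outside [1, 3]."""


class ZeroVarianceError(MirtempoError, ValueError):
    """Pearson correlation undefined because a vector is constant."""


class DegenerateDesignError(MirtempoError, ValueError):
    """Linear fit requested with fewer than 3 design points or constant x."""


class InvalidDfError(MirtempoError, ValueError):
    """Non-positive degrees of freedom for an F probability."""


class TooFewTimePointsError(MirtempoError, ValueError):
    """ANOVA grouping requires at least 4 time points."""


class ZeroWithinGroupVarianceError(MirtempoError, ValueError):
    """Welch ANOVA weights undefined: a group has zero variance."""


class DimensionMismatchError(MirtempoError, ValueError):
    """Two matrices that must align do not."""


class NonPositiveNError(MirtempoError, ValueError):
    """Reference-normal vector requested with n < 1."""


class InvalidSpecError(MirtempoError, ValueError):
    """Synthetic-data specification violates its invariants."""


class UnreachableTargetError(MirtempoError, ValueError):
    """Replicate-correlation calibration cannot reach the requested r."""


class UnwritablePathError(MirtempoError, OSError):
    """An output path could not be written."""
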