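"""Exception hierarchy.

Errors are split into configuration problems (bad user input to the
pipeline), data problems (a cohort file that violates the schema or
contains unusable values), and numeric problems (degenerate matrices or
undefined transforms encountered during fitting).
"""


class CurvegradeError(Exception):
    """Base class for all package errors."""


class ConfigError(CurvegradeError):
    """Invalid configuration (grid, pipeline config, generative spec)."""


class SchemaError(CurvegradeError):
    """A required column is missing or mis-typed in an input table."""


class DataError(CurvegradeError):
    """A cell-level data problem: missing value, non-numeric entry."""


class DegenerateVarianceError(DataError):
    """A column used as a variable has zero (or negative) variance."""


class DegenerateIntervalError(CurvegradeError):
    """A confidence interval is undefined (e.g. |r| = 1 for Fisher CI)."""


class MatrixError(CurvegradeError):
    """A correlation/covariance matrix is invalid or singular."""


class CollinearityError(MatrixError):
    """A design matrix is rank deficient."""


class DomainError(CurvegradeError):
    """A power transform was requested outside its domain
    (non-positive base with a fractional exponent)."""


class NumericError(CurvegradeError):
    """An iterative procedure hit a numerically invalid state."""
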