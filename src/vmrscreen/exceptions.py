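"""Exception hierarchy shared across the package."""


class VMRScreenError(Exception):
    """Base class for all package-specific errors."""


class TraceFormatError(VMRScreenError, ValueError):
    """A trace table violates the file contract (missing column, negative
    displacement, duplicated (well, second) row, ragged time grid)."""


class ProtocolError(VMRScreenError, ValueError):
    """A stimulus protocol is malformed or lacks the required light-off event."""


class WindowRangeError(VMRScreenError, ValueError):
    """An analysis window extends beyond the recorded time grid."""


class InsufficientSampleError(VMRScreenError, ValueError):
    """Fewer observations than a procedure requires (e.g. < 2 larvae per group)."""


class DomainError(VMRScreenError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class SingularCovarianceError(VMRScreenError, ValueError):
    """The pooled covariance matrix is singular and cannot be inverted."""


class DimensionError(VMRScreenError, ValueError):
    """The vector dimension is incompatible with the sample sizes of a test."""


class UndefinedStatisticError(VMRScreenError, ValueError):
    """A test statistic is undefined for the given input (e.g. zero variance)."""


class DegenerateTableError(VMRScreenError, ValueError):
    """A contingency table has a zero margin."""


class DesignError(VMRScreenError, ValueError):
    """A screen design is internally inconsistent (e.g. missing vehicle wells)."""


class MappingError(VMRScreenError, KeyError):
    """Data contain a factor level that a fitted model has never seen."""


class FitError(VMRScreenError, ValueError):
    """A curve fit failed to converge or the data carry no signal to fit."""
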