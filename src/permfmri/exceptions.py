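"""Exception hierarchy shared by all permfmri modules."""


class PermfmriError(Exception):
    """Base class for all errors raised by permfmri."""


class DimensionalityError(PermfmriError):
    """An array does not have the expected number of dimensions."""


class ShapeError(PermfmriError):
    """Array shapes are mutually inconsistent."""


class LengthError(PermfmriError):
    """A time series is too short for the requested operation."""


class DomainError(PermfmriError):
    """An argument lies outside the mathematical domain of the operation."""


class EmptyMaskError(PermfmriError):
    """A brain mask (or certainty field) contains no usable voxels."""


class StationarityError(PermfmriError):
    """AR coefficients describe a non-stationary (unstable) process."""


class DegenerateSeriesError(PermfmriError):
    """A time series is degenerate (e.g. constant) for the fit requested."""


class DegenerateDesignError(PermfmriError):
    """The design matrix is degenerate (rank deficient or all-zero)."""


class DegeneracyError(PermfmriError):
    """A covariance or constraint system is degenerate beyond repair."""


class ResolutionError(PermfmriError):
    """A kernel or grid parameter is below the representable resolution."""
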