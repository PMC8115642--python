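"""Exception types shared across the package."""


class DcewashError(Exception):
    """Base class for all package-specific errors."""


class InvalidSampleError(DcewashError):
    """A kinetic sample is unusable, e.g. non-positive pre-contrast signal."""


class EmptyLesionError(DcewashError):
    """The lesion mask contains no voxels (radiological complete response)."""


class NoPlacementError(DcewashError):
    """No ROI disc of the requested diameter fits inside the lesion mask."""


class NotEvaluableError(DcewashError):
    """An observation cannot be scored (residual lesion without kinetics)."""


class InvalidBaselineError(DcewashError):
    """Baseline lesion size is non-positive; RECIST change is undefined."""


class UndefinedStatisticError(DcewashError):
    """A statistic has no value on this input (e.g. constant sequence)."""


class GridMismatchError(DcewashError):
    """Phase volumes / mask do not share grid shape or voxel spacing."""


class SchemaError(DcewashError):
    """A cohort table is missing required columns."""


class ConvergenceError(DcewashError):
    """Model fitting failed to converge (e.g. monotone Cox likelihood)."""
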