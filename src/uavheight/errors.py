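"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`UAVHeightError`
so callers can catch pipeline failures without masking programming errors.
"""


class UAVHeightError(Exception):
    """Base class for all errors raised by uavheight."""


class LayoutError(UAVHeightError):
    """Field layout is inconsistent or does not fit its analysis region."""


class SeasonConflictError(UAVHeightError):
    """A canopy was supplied for a pre-germination (bare ground) flight."""


class EmptyROIError(UAVHeightError):
    """No pixel centers fall inside the ROI rectangle."""


class DegradedROIError(UAVHeightError):
    """Too large a fraction of the ROI is nodata to trust its statistics."""


class GridAlignmentError(UAVHeightError):
    """Two rasters do not share origin, pixel size and shape."""


class RankDeficiencyError(UAVHeightError):
    """The polynomial-surface design matrix is rank deficient (underdetermined
    or degenerate point geometry); refusing to return a minimum-norm fit."""


class UndefinedCorrelationError(UAVHeightError):
    """Pearson correlation requested on data with zero variance."""


class DegenerateRegressionError(UAVHeightError):
    """Linear calibration requested on a constant predictor."""


class IncompleteDesignError(UAVHeightError):
    """A cross-validation partition has no samples for some (flight, group)."""
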