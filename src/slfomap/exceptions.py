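"""Exception hierarchy for the sLFO mapping pipeline.

Every error raised on a violated contract derives from :class:`SlfomapError`
so callers can catch pipeline failures without masking programming errors.
"""


class SlfomapError(ValueError):
    """Base class for all contract violations in this package."""


class InvalidBandError(SlfomapError):
    """Frequency band is empty, non-positive, or extends past Nyquist."""


class InvalidLengthError(SlfomapError):
    """Timeseries too short for the requested operation."""


class GeometryError(SlfomapError):
    """Phantom grid too small to realize a non-empty tissue geometry."""


class CohortSizeError(SlfomapError):
    """Cohort operations need at least two subjects."""


class CohortCompatibilityError(SlfomapError):
    """Subjects in a cohort disagree on TR or number of timepoints."""


class ShapeError(SlfomapError):
    """Array grids or sequence lengths do not match."""


class EmptyRoiError(SlfomapError):
    """A region of interest contains no voxels."""


class SamplingError(SlfomapError):
    """Sampling intervals (TR) of two inputs disagree."""


class InsufficientVoxelsError(SlfomapError):
    """Fewer valid voxels than bins requested."""


class ParameterError(SlfomapError):
    """A scalar parameter is outside its admissible range."""
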