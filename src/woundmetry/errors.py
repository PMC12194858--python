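"""Exception hierarchy shared across the measurement pipeline."""


class WoundmetryError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(WoundmetryError, ValueError):
    """An image, mask or structuring element violates a precondition."""


class DegenerateHistogramError(WoundmetryError):
    """Otsu thresholding was asked to split a constant image."""


class FiducialNotFoundError(WoundmetryError):
    """No component survived the fiducial detection filters.

    Carries the candidate component statistics considered before
    filtering, for diagnosis.
    """

    def __init__(self, message, candidate_stats=None):
        super().__init__(message)
        self.candidate_stats = candidate_stats or []


class AmbiguousFiducialError(WoundmetryError):
    """Two or more candidates tied exactly under the ranking score."""

    def __init__(self, message, candidate_stats=None):
        super().__init__(message)
        self.candidate_stats = candidate_stats or []


class DegenerateClusteringError(WoundmetryError):
    """K-means was asked for more clusters than distinct feature vectors."""


class AmbiguousClusterError(WoundmetryError):
    """The wound-cluster selection rule could not break a tie."""


class DegenerateStatisticsError(WoundmetryError):
    """A statistical test met a zero-variance (undefined) configuration."""


class InvalidSpecError(WoundmetryError, ValueError):
    """A synthetic scene specification is geometrically impossible."""


class ConfigError(WoundmetryError, ValueError):
    """A run configuration is malformed."""
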