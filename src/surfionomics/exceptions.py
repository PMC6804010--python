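"""Exception hierarchy for the surfionomics pipeline."""


class SurfionomicsError(Exception):
    """Base class for all package-specific errors."""


class BitDepthError(SurfionomicsError):
    """Raised for rasters that are not 8-bit."""


class DegenerateImageError(SurfionomicsError):
    """Raised when an image is constant and a histogram-based statistic is undefined."""


class EmptySitesError(SurfionomicsError):
    """Raised when a site mask contains no foreground to take fractions over."""


class OverlapPlacementError(SurfionomicsError):
    """Raised when non-overlapping aggregate placement fails after bounded retries."""


class InfeasibleCoverageError(SurfionomicsError):
    """Raised when a requested co-location coverage cannot be realized."""


class StageError(SurfionomicsError):
    """Raised by the pipeline with the failing stage name and input identifier."""

    def __init__(self, stage: str, input_id: str, cause: Exception):
        self.stage = stage
        self.input_id = input_id
        self.cause = cause
        super().__init__(f"stage {stage!r} failed on input {input_id!r}: {cause}")
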