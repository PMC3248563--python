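"""Exception hierarchy shared across the pipeline.

Two broad families map onto the CLI exit codes: :class:`InputError` (exit 2)
for malformed or missing inputs, and :class:`DegenerateDataError` (exit 3) for
inputs that parse but cannot support the requested computation (a constant
image, a zero-length body, a zero control mean, ...).
"""


class WormTriageError(Exception):
    """Base class for all errors raised by wormtriage."""

    exit_code = 1


class InputError(WormTriageError):
    """Malformed, missing, or inconsistent input."""

    exit_code = 2


class DegenerateDataError(WormTriageError):
    """Structurally valid input on which the computation is undefined."""

    exit_code = 3


class DimensionError(InputError):
    """Array shapes do not line up."""


class InputStructureError(InputError):
    """Input container violates the required structure (e.g. frame gaps)."""


class CalibrationRequiredError(InputError):
    """A physical calibration (pixel size, frame interval) was not supplied."""


class IncompleteRecordError(InputError):
    """A gene record lacks the data required by a triage stage."""


class InsufficientReplicatesError(InputError):
    """Too few replicates to compute the requested statistic or verdict."""


class PairingError(InputError):
    """A sample is missing its reference-gene measurements."""


class DegenerateFrameError(DegenerateDataError):
    """A video frame has zero mean intensity and cannot be rescaled."""

    def __init__(self, frame_index: int):
        self.frame_index = frame_index
        super().__init__(f"frame {frame_index} has zero mean intensity")


class InsufficientFramesError(DegenerateDataError):
    """Background estimation needs at least two frames."""


class NoContrastError(DegenerateDataError):
    """A constant image has no threshold."""


class ZeroBodyLengthError(DegenerateDataError):
    """Every blob in a track is degenerate; no body length is defined."""


class DivisionGuardError(DegenerateDataError):
    """Zero body length or zero duration in a speed computation."""


class NormalizationError(DegenerateDataError):
    """Pre-bleach intensities are zero; the RFI normalization is undefined."""


class UndefinedReductionError(DegenerateDataError):
    """Control mean is zero; fractional reductions are undefined."""


class NoDataError(DegenerateDataError):
    """An empty collection where at least one observation is required."""


class PoolingRequiredError(DegenerateDataError):
    """A chi-square class has expected count < 1 and must be merged upstream."""


class GeometryError(InputError):
    """Simulation arena cannot accommodate the requested worm geometry."""
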