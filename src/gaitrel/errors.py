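"""Exception and warning types shared across the package."""


class GaitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GaitError, ValueError):
    """A value violates a documented invariant; the message names the field."""


class AlignmentError(GaitError, ValueError):
    """Trajectories that must share frame count / frame rate do not."""


class GenerationError(GaitError, ValueError):
    """A synthetic trial cannot be generated under the requested parameters."""


class MissingSegmentError(GaitError, KeyError):
    """A required segment trajectory is absent from a trial."""


class InsufficientProgressionError(GaitError, ValueError):
    """Net horizontal pelvis displacement is too small to define a direction."""


class CycleRangeError(GaitError, ValueError):
    """A gait-cycle window falls outside the sampled time range."""


class IncompleteMatrixError(GaitError, ValueError):
    """A measurement matrix contains missing cells; a complete design is required."""


class SchemaError(GaitError, ValueError):
    """A dataset file violates the JSON dataset schema; message carries a JSON pointer."""


class TrialProcessingError(GaitError, RuntimeError):
    """A single trial failed event detection or cycle assembly."""


class GimbalLockWarning(UserWarning):
    """The middle Cardan angle is within 1 degree of +/-90 degrees."""


class DegenerateInputWarning(UserWarning):
    """A statistic was computed on input with no variance; the value is by convention."""
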