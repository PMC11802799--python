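"""Exception and warning hierarchy for srclock.

Errors correspond to well-defined failure modes of the phase-resetting
model and the estimation pipeline (singular states, undersampled curves,
saturated dose-response inversions, ...) rather than generic ValueErrors,
so callers can handle them selectively.
"""


class SrclockError(Exception):
    """Base class for all srclock errors."""


class SingularityError(SrclockError):
    """The post-stimulus state lies at (or within tolerance of) the
    amplitude-zero singular point, where phase is undefined."""


class AmbiguousPrcError(SrclockError):
    """Winding number of the post-stimulus phase map is too far from an
    integer; the PRC is undersampled or inconsistent."""


class EmptyRecordsError(SrclockError):
    """No records supplied where at least one is required."""


class DetrendError(SrclockError):
    """Detrending failed (too short a series, or too many nonpositive
    moving-average points)."""


class DegenerateSignalError(SrclockError):
    """Fit window carries no usable rhythm (variance below noise floor)."""


class NonConvergenceError(SrclockError):
    """An iterative fit failed to converge after bounded restarts."""


class OutOfRangeError(SrclockError):
    """Requested SR amplitude exceeds the achievable ceiling of the
    forward amplitude map."""

    def __init__(self, message, *, ceiling=None, F_max=None):
        super().__init__(message)
        self.ceiling = ceiling
        self.F_max = F_max


class SaturatedError(SrclockError):
    """SR amplitude at or above the Hill saturation limit: the equivalent
    concentration is infinite."""


class NotInhibitoryError(SrclockError):
    """Final response is not smaller than the background response, so the
    antagonist rule does not apply."""


class WrapAmbiguousError(SrclockError):
    """Phase spread exceeds pi after unwrapping; a straight-line phase fit
    would be meaningless."""


class ZeroVarianceError(SrclockError):
    """All observed values equal; the coefficient of determination is
    undefined."""


class AllZeroError(SrclockError):
    """No positive response in a dose-response table; normalization by the
    maximum is impossible."""


class ParseError(SrclockError):
    """A file failed validation; the message carries the offending line."""


class NonuniformSamplingError(SrclockError):
    """A time series violates the uniform-sampling contract."""


class MissingSidecarError(SrclockError):
    """Plate CSV supplied without the per-well metadata sidecar."""


# ---------------------------------------------------------------------------
# Warnings


class SrclockWarning(UserWarning):
    """Base class for all srclock warnings."""


class UndersampledWarning(SrclockWarning):
    """Fewer quadrature nodes than needed for a reliable SR estimate."""


class NonMonotoneWarning(SrclockWarning):
    """Dose response decreases substantially at high dose; the Hill model
    may be inappropriate (cytotoxicity-like behavior)."""


class CapBiasWarning(SrclockWarning):
    """A capped amplitude entered a subtraction; the result may be biased."""


class ExtrapolationWarning(SrclockWarning):
    """Prediction requested outside the fitted concentration range."""


class SingularNodeWarning(SrclockWarning):
    """A quadrature node fell on the singular point and the grid was
    shifted by half a step."""
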