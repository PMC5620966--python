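"""Exception hierarchy for kneekin.

All errors derive from :class:`KneeKinError` so callers can catch the whole
family; most also derive from ``ValueError`` since they signal bad inputs.
"""


class KneeKinError(Exception):
    """Base class for all kneekin errors."""


class InvalidInputError(KneeKinError, ValueError):
    """Non-finite, mis-shaped, or otherwise malformed numeric input."""


class DegenerateGeometryError(KneeKinError, ValueError):
    """Geometric construction is undefined (antiparallel axes, parallel triad)."""


class InsufficientSignalError(KneeKinError, ValueError):
    """Signal content too weak for the requested estimate (e.g. motionless sync)."""


class NotStillError(KneeKinError, ValueError):
    """A supposed still interval shows too much acceleration deviation."""


class PoorCalibrationError(KneeKinError, ValueError):
    """Functional calibration failed (no excitation, no convergence, high residual)."""


class CalibrationRequiredError(KneeKinError, ValueError):
    """Operation needs calibration data (reference still, hinge axes) not supplied."""


class NoAnchorError(KneeKinError, ValueError):
    """No hinge update interval in the recording; the correction is undefined."""


class GridMismatchError(KneeKinError, ValueError):
    """Series expected on a common time grid do not share one."""
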