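"""Per-sample hinge classification.

The world-frame correction may only be updated while the knee functions
predominantly as a hinge.  Two cases qualify:

* **Case 1a — stationary hinge**: both segments stationary and near the
  calibration (vertical) pose.  Both sensors' windowed-mean acceleration
  magnitude must stay within ``accel_mag_tol * g`` of gravity, and the mean
  over the two sensors of the angle between the current windowed-mean
  acceleration and the reference still acceleration ``a0`` must not exceed
  ``accel_angle_tol`` degrees.
* **Case 1b — rotating hinge**: both angular-rate magnitudes at least
  ``omega_min`` and the mean over the two sensors of the alignment cosine
  between the rate vector and the hinge axis above ``axis_alignment_min``.
  By default the absolute cosine is used so that the criterion is indifferent
  to the direction of hinge rotation; signed projections are available via
  ``signed_projection``.

Every remaining sample is Case 2 (not a hinge); the correction is
interpolated across those gaps.  Criteria are evaluated on centered
sliding-window means (default 0.1 s) to suppress sample-level noise chatter;
a one-sample window recovers the instantaneous criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .calibration import AnatomicalCalibration
from .errors import CalibrationRequiredError, GridMismatchError, NoAnchorError
from .streams import GRAVITY, ImuStream, IntervalSet

__all__ = ["HingeThresholds", "HingeStatus", "detect_stationary",
           "detect_rotating", "detect_hinge", "update_intervals"]


@dataclass(frozen=True)
class HingeThresholds:
    """Detection thresholds; defaults are the stringent knee-analog values
    (they would need to be relaxed for human subjects)."""

    accel_mag_tol: float = 0.02       # fraction of g
    accel_angle_tol: float = 3.0      # degrees
    omega_min: float = 30.0           # deg/s
    axis_alignment_min: float = 0.99  # cosine
    window: float = 0.1               # seconds, centered mean
    signed_projection: bool = False

    def __post_init__(self):
        if min(self.accel_mag_tol, self.accel_angle_tol, self.omega_min, self.window) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.axis_alignment_min <= 1.0:
            raise ValueError("axis_alignment_min must lie in (0, 1]")


@dataclass
class HingeStatus:
    """Boolean classification series; the update set is ``case1a | case1b``."""

    t: np.ndarray
    case1a: np.ndarray
    case1b: np.ndarray

    @property
    def update_mask(self) -> np.ndarray:
        return self.case1a | self.case1b

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_s": self.t, "case1a": self.case1a.astype(int), "case1b": self.case1b.astype(int)}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _windowed_mean(x: np.ndarray, fs: float, window: float) -> np.ndarray:
    size = max(1, int(round(window * fs)))
    if size == 1:
        return x
    return uniform_filter1d(x, size=size, axis=0, mode="nearest")


def _check_pair(stream_s: ImuStream, stream_t: ImuStream):
    if len(stream_s) != len(stream_t) or not np.allclose(stream_s.t, stream_t.t, atol=1e-9):
        raise GridMismatchError("streams must share one time grid for hinge detection")


def _angle_deg(a: np.ndarray, ref: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1)
    nr = np.linalg.norm(ref)
    cosang = np.clip(a @ ref / np.maximum(na * nr, 1e-12), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def detect_stationary(
    stream_s: ImuStream,
    stream_t: ImuStream,
    calib_s: AnatomicalCalibration,
    calib_t: AnatomicalCalibration,
    th: HingeThresholds = HingeThresholds(),
    g: float = GRAVITY,
) -> np.ndarray:
    """Case 1a: stationary near the calibration pose (see module docstring)."""
    _check_pair(stream_s, stream_t)
    for cal, name in ((calib_s, "shank"), (calib_t, "thigh")):
        if cal.a0 is None:
            raise CalibrationRequiredError(f"{name} calibration lacks the reference still a0")
    fs = stream_s.fs
    a_s = _windowed_mean(stream_s.accel, fs, th.window)
    a_t = _windowed_mean(stream_t.accel, fs, th.window)
    dev_s = np.abs(np.linalg.norm(a_s, axis=1) - g)
    dev_t = np.abs(np.linalg.norm(a_t, axis=1) - g)
    mag_ok = np.maximum(dev_s, dev_t) <= th.accel_mag_tol * g
    mean_angle = 0.5 * (_angle_deg(a_s, calib_s.a0) + _angle_deg(a_t, calib_t.a0))
    return mag_ok & (mean_angle <= th.accel_angle_tol)


def detect_rotating(
    stream_s: ImuStream,
    stream_t: ImuStream,
    calib_s: AnatomicalCalibration,
    calib_t: AnatomicalCalibration,
    th: HingeThresholds = HingeThresholds(),
) -> np.ndarray:
    """Case 1b: both segments rotating predominantly about the hinge axis."""
    _check_pair(stream_s, stream_t)
    fs = stream_s.fs
    w_s = _windowed_mean(stream_s.gyro, fs, th.window)
    w_t = _windowed_mean(stream_t.gyro, fs, th.window)
    mag_s = np.linalg.norm(w_s, axis=1)
    mag_t = np.linalg.norm(w_t, axis=1)
    fast = np.minimum(mag_s, mag_t) >= np.deg2rad(th.omega_min)
    cos_s = w_s @ calib_s.n_hat / np.maximum(mag_s, 1e-12)
    cos_t = w_t @ calib_t.n_hat / np.maximum(mag_t, 1e-12)
    if not th.signed_projection:
        cos_s, cos_t = np.abs(cos_s), np.abs(cos_t)
    aligned = 0.5 * (cos_s + cos_t) > th.axis_alignment_min
    return fast & aligned


def detect_hinge(
    stream_s: ImuStream,
    stream_t: ImuStream,
    calib_s: AnatomicalCalibration,
    calib_t: AnatomicalCalibration,
    th: HingeThresholds = HingeThresholds(),
) -> HingeStatus:
    """Evaluate both cases independently over the full recording."""
    return HingeStatus(
        t=np.asarray(stream_s.t, dtype=float),
        case1a=detect_stationary(stream_s, stream_t, calib_s, calib_t, th),
        case1b=detect_rotating(stream_s, stream_t, calib_s, calib_t, th),
    )


def update_intervals(status: HingeStatus) -> IntervalSet:
    """Maximal contiguous runs where either case holds (the 'update' times).

    The gaps between runs are the Case-2 spans bridged by interpolation.
    An entirely hinge-free recording admits no correction at all.
    """
    mask = status.update_mask
    if not mask.any():
        raise NoAnchorError("no sample satisfies either hinge criterion")
    return IntervalSet.from_mask(status.t, mask)
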