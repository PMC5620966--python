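"""Functional sensor-to-segment calibration.

Two alignment movements locate each segment's anatomical axes in its own
sensor frame:

1. a still period with the segment vertical — the mean measured acceleration
   gives the gravity direction, a first estimate of the superior-inferior
   axis ``Z_A``, and the reference still acceleration ``a0``;
2. pure hinge (flexion/extension) rotations — the two sensors' angular rates
   identify the common medial-lateral hinge axis ``n`` in each sensor frame.

The anatomical triad is then ``X_A = n``, ``Y_A = normalize(Z_est x X_A)``,
``Z_A = X_A x Y_A`` (the superior-inferior estimate is re-orthogonalized so
the triad is exactly orthonormal), and the constant sensor-to-anatomical DCM
stacks the triad row-wise.

The hinge axis is found by minimizing the symmetric joint-axis cost

    sum_i ( |w_S(t_i) x n_S| - |w_T(t_i) x n_T| )^2

over spherical coordinates of the two unit axes (Levenberg-Marquardt),
initialized from each sensor's principal angular-rate direction.  For a true
hinge the perpendicular rate components of the two segments have equal
magnitude at every instant, so the cost vanishes at the true axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares

from .errors import (
    DegenerateGeometryError,
    InsufficientSignalError,
    InvalidInputError,
    NotStillError,
    PoorCalibrationError,
)
from .streams import GRAVITY, ImuStream, IntervalSet

__all__ = [
    "AnatomicalCalibration",
    "synchronize",
    "detect_still_intervals",
    "estimate_vertical_axis",
    "estimate_hinge_axis",
    "build_anatomical_frame",
    "calibrate_pair",
]


@dataclass
class AnatomicalCalibration:
    """Anatomical axes of one segment, expressed in its sensor frame.

    ``R`` is the constant DCM from sensor to anatomical coordinates with rows
    exactly ``(x_axis, y_axis, z_axis)``; ``n_hat`` (the hinge / medial-lateral
    axis) equals ``x_axis``.  ``a0`` is the reference acceleration measured
    during the calibration still, used by the stationary hinge criterion.
    """

    n_hat: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    R: np.ndarray
    a0: np.ndarray | None = None
    meta: dict | None = None

    def __post_init__(self):
        for name in ("n_hat", "x_axis", "y_axis", "z_axis", "R"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.a0 is not None:
            self.a0 = np.asarray(self.a0, dtype=float)
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-9):
            raise InvalidInputError("sensor-to-anatomical DCM not orthonormal")
        if not np.allclose(self.R, np.vstack([self.x_axis, self.y_axis, self.z_axis]), atol=1e-12):
            raise InvalidInputError("DCM rows must equal the anatomical axes")

    def to_json(self, path) -> None:
        payload = {
            "n_hat": self.n_hat.tolist(),
            "x_axis": self.x_axis.tolist(),
            "y_axis": self.y_axis.tolist(),
            "z_axis": self.z_axis.tolist(),
            "R": self.R.tolist(),
            "a0": None if self.a0 is None else self.a0.tolist(),
            "meta": self.meta or {},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AnatomicalCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["n_hat"], d["x_axis"], d["y_axis"], d["z_axis"], d["R"],
            d.get("a0"), d.get("meta") or None,
        )


def _rate_magnitude(stream: ImuStream) -> np.ndarray:
    return np.linalg.norm(stream.gyro, axis=1)


def synchronize(
    stream_a: ImuStream,
    stream_b: ImuStream,
    max_lag: float | None = None,
    min_peak_rate: float = np.deg2rad(10.0),
) -> float:
    """Time delay of ``stream_b`` relative to ``stream_a``, seconds.

    Cross-correlates the two angular-rate magnitude signals and refines the
    peak to sub-sample resolution by parabolic interpolation.  A positive lag
    means the shared motion appears ``lag`` seconds later in ``stream_b``;
    shifting ``stream_b`` by ``-lag`` aligns the signals.
    """
    dt = 1.0 / stream_a.fs
    if abs(stream_b.fs - stream_a.fs) > 0.01 * stream_a.fs:
        raise InvalidInputError("streams must share a sample rate before synchronization")
    sa = _rate_magnitude(stream_a)
    sb = _rate_magnitude(stream_b)
    if sa.max() < min_peak_rate or sb.max() < min_peak_rate:
        raise InsufficientSignalError(
            "angular-rate magnitudes too small for cross-correlation sync"
        )
    sa = sa - sa.mean()
    sb = sb - sb.mean()
    corr = signal.correlate(sb, sa, mode="full")
    lags = signal.correlation_lags(len(sb), len(sa), mode="full")
    if max_lag is not None:
        keep = np.abs(lags * dt) <= max_lag
        corr, lags = corr[keep], lags[keep]
    k = int(np.argmax(corr))
    lag = float(lags[k])
    # parabolic sub-sample refinement around the discrete peak
    if 0 < k < len(corr) - 1:
        y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-30:
            lag += float(0.5 * (y0 - y2) / denom)
    return lag * dt


def detect_still_intervals(
    stream: ImuStream,
    accel_tol: float = 0.02,
    gyro_max_deg_s: float = 2.0,
    min_duration: float = 1.0,
    smooth: float = 0.5,
    g: float = GRAVITY,
) -> IntervalSet:
    """Automatic still detector: low-passed accel magnitude within
    ``accel_tol * g`` of gravity AND low-passed gyro magnitude below
    ``gyro_max_deg_s``, sustained for at least ``min_duration`` seconds."""
    fs = stream.fs
    w = max(1, int(round(smooth * fs)))
    acc = uniform_filter1d(stream.accel, size=w, axis=0, mode="nearest")
    gyr = uniform_filter1d(stream.gyro, size=w, axis=0, mode="nearest")
    ok = (np.abs(np.linalg.norm(acc, axis=1) - g) <= accel_tol * g) & (
        np.linalg.norm(gyr, axis=1) <= np.deg2rad(gyro_max_deg_s)
    )
    runs = IntervalSet.from_mask(stream.t, ok)
    return IntervalSet(tuple(iv for iv in runs if iv[1] - iv[0] >= min_duration))


def estimate_vertical_axis(stream: ImuStream, still, g: float = GRAVITY):
    """Gravity direction over a still interval.

    Returns ``(z_hat, a0)``: the normalized mean acceleration (first estimate
    of the superior-inferior anatomical axis in sensor coordinates) and the
    mean acceleration vector itself (the Case-1a reference still ``a0``).
    """
    if not isinstance(still, IntervalSet):
        still = IntervalSet((tuple(still),))
    m = still.mask(stream.t)
    if m.sum() < 2:
        raise NotStillError("still interval contains too few samples")
    a0 = stream.accel[m].mean(axis=0)
    mag = float(np.linalg.norm(a0))
    if abs(mag - g) > 0.05 * g:
        raise NotStillError(
            f"mean accel magnitude {mag:.3f} deviates from g by more than 5%"
        )
    return a0 / mag, a0


def _sph_to_unit(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _unit_to_sph(v: np.ndarray):
    v = v / np.linalg.norm(v)
    return float(np.arccos(np.clip(v[2], -1, 1))), float(np.arctan2(v[1], v[0]))


def _principal_direction(w: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(w.T @ w)
    return vecs[:, -1]


def estimate_hinge_axis(
    stream_s: ImuStream,
    stream_t: ImuStream,
    hinge_motion,
    min_peak_rate_deg_s: float = 30.0,
    residual_max_deg_s: float = 5.0,
    max_iter: int = 200,
    medial_hint_s=None,
    medial_hint_t=None,
):
    """Per-sensor hinge (medial-lateral) axes from a pure-hinge movement.

    Returns ``(n_s, n_t)``, unit vectors in the respective sensor frames.

    Sign convention: the medially pointing direction cannot be inferred from
    rates alone, so an approximate medial direction per sensor may be given
    (``medial_hint_*``; only its sign matters).  Without hints, the axes are
    made mutually consistent through the streams' reported world orientations
    (assuming the inter-sensor heading misalignment is below 90 deg), with the
    shank's principal rate direction taken as positive.
    """
    if not isinstance(hinge_motion, IntervalSet):
        hinge_motion = IntervalSet((tuple(hinge_motion),))
    ms = hinge_motion.mask(stream_s.t)
    mt = hinge_motion.mask(stream_t.t)
    ws = stream_s.gyro[ms]
    wt = stream_t.gyro[mt]
    if len(ws) != len(wt):
        n = min(len(ws), len(wt))
        ws, wt = ws[:n], wt[:n]
    if len(ws) < 10:
        raise PoorCalibrationError("hinge interval contains too few samples")
    peak = min(np.linalg.norm(ws, axis=1).max(), np.linalg.norm(wt, axis=1).max())
    if peak < np.deg2rad(min_peak_rate_deg_s):
        raise PoorCalibrationError(
            f"hinge excitation too weak (peak {np.rad2deg(peak):.1f} deg/s)"
        )

    def residuals(p):
        ns = _sph_to_unit(p[0], p[1])
        nt = _sph_to_unit(p[2], p[3])
        return np.linalg.norm(np.cross(ws, ns), axis=1) - np.linalg.norm(
            np.cross(wt, nt), axis=1
        )

    x0 = np.array([*_unit_to_sph(_principal_direction(ws)), *_unit_to_sph(_principal_direction(wt))])
    sol = least_squares(
        residuals, x0, method="lm", max_nfev=max_iter * (len(x0) + 1),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if sol.status <= 0:
        raise PoorCalibrationError("hinge-axis solver did not converge")
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    if rms > np.deg2rad(residual_max_deg_s):
        raise PoorCalibrationError(
            f"hinge-axis residual {np.rad2deg(rms):.2f} deg/s exceeds threshold"
        )
    n_s = _sph_to_unit(sol.x[0], sol.x[1])
    n_t = _sph_to_unit(sol.x[2], sol.x[3])

    if medial_hint_s is not None:
        if np.dot(n_s, np.asarray(medial_hint_s, float)) < 0:
            n_s = -n_s
    if medial_hint_t is not None:
        if np.dot(n_t, np.asarray(medial_hint_t, float)) < 0:
            n_t = -n_t
    if medial_hint_s is None and medial_hint_t is None:
        if np.dot(n_s, _principal_direction(ws)) < 0:
            n_s = -n_s
        if stream_s.quat is not None and stream_t.quat is not None:
            i_s = int(np.flatnonzero(ms)[0])
            i_t = int(np.flatnonzero(mt)[0])
            u = stream_s.world_dcms()[i_s] @ n_s
            v = stream_t.world_dcms()[i_t] @ n_t
            if np.dot(u, v) < 0:
                n_t = -n_t
        elif np.dot(n_t, _principal_direction(wt)) < 0:
            n_t = -n_t
    elif medial_hint_s is None or medial_hint_t is None:
        raise InvalidInputError("give both medial hints or neither")
    return n_s, n_t


def build_anatomical_frame(
    z_est, n_hat, a0=None, min_angle_deg: float = 10.0, meta: dict | None = None
) -> AnatomicalCalibration:
    """Assemble the orthonormal anatomical triad and sensor-to-anatomical DCM.

    ``X_A = n_hat`` (hinge axis), ``Y_A = normalize(z_est x X_A)``,
    ``Z_A = X_A x Y_A``; rows of the DCM are the triad.  The vertical estimate
    is thereby re-orthogonalized against the hinge axis.
    """
    z_est = np.asarray(z_est, dtype=float)
    z_est = z_est / np.linalg.norm(z_est)
    x = np.asarray(n_hat, dtype=float)
    x = x / np.linalg.norm(x)
    cross = np.cross(z_est, x)
    if np.linalg.norm(cross) < np.sin(np.deg2rad(min_angle_deg)):
        raise DegenerateGeometryError(
            "vertical and hinge axes nearly parallel; calibration geometry degenerate"
        )
    y = cross / np.linalg.norm(cross)
    z = np.cross(x, y)
    R = np.vstack([x, y, z])
    return AnatomicalCalibration(x, x, y, z, R, a0=a0, meta=meta)


def calibrate_pair(
    stream_s: ImuStream,
    stream_t: ImuStream,
    still,
    hinge_motion,
    medial_hint_s=None,
    medial_hint_t=None,
):
    """Run the full functional alignment for a shank/thigh stream pair.

    Returns ``(calib_shank, calib_thigh)``.
    """
    z_s, a0_s = estimate_vertical_axis(stream_s, still)
    z_t, a0_t = estimate_vertical_axis(stream_t, still)
    n_s, n_t = estimate_hinge_axis(
        stream_s, stream_t, hinge_motion,
        medial_hint_s=medial_hint_s, medial_hint_t=medial_hint_t,
    )
    cal_s = build_anatomical_frame(z_s, n_s, a0=a0_s, meta={"segment": "shank"})
    cal_t = build_anatomical_frame(z_t, n_t, a0=a0_t, meta={"segment": "thigh"})
    return cal_s, cal_t
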