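"""Synthetic two-link knee-analog generator.

Emulates an encoder-instrumented mechanical linkage exercised by hand: two
rigid links coupled by a 3-DOF joint (abduction-adduction about Y, then
internal-external rotation about Z, then flexion-extension about X, in series
from the shank link to the thigh link), with an IMU rigidly mounted on each
link at an arbitrary orientation.

Each recording follows the scripted protocol of the physical experiment:

====================  =======================================================
phase                 content
====================  =======================================================
``still_pre``         both links vertical and stationary (reference still)
``calibration``       pure-hinge FE oscillation, split between the two links,
                      plus a small two-axis whole-assembly wobble (the wobble
                      provides the perpendicular rate content that makes the
                      hinge-axis cost identifiable)
``still_mid``         short still
``motion``            the trial movement: tilt ramp in, prescribed joint
                      trajectories, tilt ramp out.  The whole assembly is held
                      at a constant base tilt during the movement, as a
                      hand-held trial is never conducted in the calibration
                      pose
``still_post``        closing still
====================  =======================================================

Joint trajectories are ramped sinusoids (raised-cosine envelopes) whose peak
excursions land exactly on the sample grid, so the truth range of motion
equals the requested amplitude exactly.

Sensor model: the gyro measures the exact body rates of its link (computed
analytically from the trajectory derivatives; manifold finite differencing is
the fallback for externally supplied orientation series) plus white noise;
the accelerometer measures gravity resolved into the sensor frame
(optionally plus lever-arm rotational terms) plus white noise; the reported
orientation quaternion is the true orientation composed with a per-sensor
world-frame heading error that starts at the configured offset and grows at
the configured drift rate — the analog of a drifting on-board filter estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .calibration import AnatomicalCalibration
from .errors import InvalidInputError
from .streams import GRAVITY, ImuStream, JointAngleSeries

__all__ = ["MOVEMENT_TYPES", "ROM_DEFAULTS", "TrialSpec", "SyntheticTrial",
           "generate_trial", "imu_from_orientation", "ramped_sin"]

MOVEMENT_TYPES = ("pure_FE", "pure_IE", "pure_AA", "combined")

#: default per-axis ranges of motion (degrees): single-axis trials use the
#: pure-rotation envelope, combined trials the 3D envelope
ROM_DEFAULTS = {
    "alignment": (0.0, 0.0, 0.0),
    "pure_FE": (161.0, 0.0, 0.0),
    "pure_IE": (0.0, 72.8, 0.0),
    "pure_AA": (0.0, 0.0, 17.0),
    "combined": (117.0, 98.4, 58.3),
}


@dataclass(frozen=True)
class TrialSpec:
    """Full parameterization of one synthetic recording.

    Angles in degrees, rates in deg/s, accelerations in m/s^2.
    ``rom_*`` default to the movement type's envelope; ``mount_*`` are DCMs
    from sensor to segment-anatomical coordinates (random if None).
    """

    movement: str = "combined"
    seed: int = 0
    fs: float = 128.0
    rom_fe: float | None = None
    rom_ie: float | None = None
    rom_aa: float | None = None
    cycles: tuple = (4, 2, 1)  # FE, IE, AA cycles within the motion hold
    still_pre: float = 10.0
    calib_duration: float = 8.0
    still_mid: float = 2.0
    trial_duration: float = 10.0
    still_post: float = 2.0
    ramp: float = 1.0  # tilt ramp in/out inside the motion phase, s
    base_tilt_deg: float = 10.0  # constant assembly tilt held during motion
    calib_rom_deg: float = 70.0
    calib_cycles: int = 4
    calib_wobble_deg: tuple = (8.0, 6.0)  # tilt (about Y) and yaw (about Z) wobble
    calib_wobble_cycles: tuple = (3, 2)
    fe_share: float = 0.5  # fraction of hinge angle carried by the shank link
    mount_shank: tuple | None = None  # R_AS_S as nested tuples, or None
    mount_thigh: tuple | None = None
    heading_offset_deg: float = 0.0  # initial thigh-vs-shank world heading offset
    drift_shank_deg_s: float = 0.0
    drift_thigh_deg_s: float = 0.0
    tilt_drift_deg_s: tuple = (0.0, 0.0)  # optional non-vertical drift component
    gyro_noise_deg_s: float = 0.0
    accel_noise_m_s2: float = 0.0
    with_mag: bool = False
    lever_arm_m: float = 0.0  # sensor offset along the segment axis; 0 = gravity-only

    def __post_init__(self):
        if self.movement not in ROM_DEFAULTS:
            raise InvalidInputError(f"unknown movement type {self.movement!r}")
        for name in ("fs", "still_pre", "calib_duration", "trial_duration"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if not 0.0 <= self.fe_share <= 1.0:
            raise InvalidInputError("fe_share must lie in [0, 1]")

    @property
    def roms(self) -> tuple:
        d = ROM_DEFAULTS[self.movement]
        return (
            d[0] if self.rom_fe is None else self.rom_fe,
            d[1] if self.rom_ie is None else self.rom_ie,
            d[2] if self.rom_aa is None else self.rom_aa,
        )


@dataclass
class SyntheticTrial:
    """A generated recording with its ground truth."""

    spec: TrialSpec
    t: np.ndarray
    truth: JointAngleSeries
    shank: ImuStream
    thigh: ImuStream
    calib_shank: AnatomicalCalibration  # ground-truth mounting calibration
    calib_thigh: AnatomicalCalibration
    heading_error_shank_deg: np.ndarray  # injected world-frame heading error
    heading_error_thigh_deg: np.ndarray
    phases: dict = field(default_factory=dict)

    @property
    def trial_window(self):
        """Motion phase plus the closing still — the validation window."""
        return (self.phases["motion"][0], self.phases["still_post"][1])


def ramped_sin(tau: np.ndarray, T: float, half_amp: float, k: int) -> np.ndarray:
    """Sinusoid of ``k`` cycles over ``[0, T]`` with raised-cosine end ramps.

    Starts and ends at zero value and zero rate; the envelope reaches 1 at the
    first sinusoid peak (``tau = T / 4k``), so the signal attains exactly
    ``+/- half_amp`` inside the flat region.
    """
    tau = np.asarray(tau, dtype=float)
    out = half_amp * np.sin(2.0 * np.pi * k * tau / T)
    d = T / (4.0 * k)
    env = np.ones_like(tau)
    lo = tau < d
    hi = tau > T - d
    env[lo] = 0.5 * (1.0 - np.cos(np.pi * tau[lo] / d))
    env[hi] = 0.5 * (1.0 - np.cos(np.pi * (T - tau[hi]) / d))
    env[(tau < 0) | (tau > T)] = 0.0
    return out * env


def _ramped_sin_vr(tau: np.ndarray, T: float, half_amp: float, k: int):
    """:func:`ramped_sin` together with its exact time derivative."""
    tau = np.asarray(tau, dtype=float)
    w = 2.0 * np.pi * k / T
    s = np.sin(w * tau)
    sd = w * np.cos(w * tau)
    d = T / (4.0 * k)
    env = np.ones_like(tau)
    envd = np.zeros_like(tau)
    lo = tau < d
    hi = tau > T - d
    env[lo] = 0.5 * (1.0 - np.cos(np.pi * tau[lo] / d))
    envd[lo] = 0.5 * np.pi / d * np.sin(np.pi * tau[lo] / d)
    env[hi] = 0.5 * (1.0 - np.cos(np.pi * (T - tau[hi]) / d))
    envd[hi] = -0.5 * np.pi / d * np.sin(np.pi * (T - tau[hi]) / d)
    out = (tau < 0) | (tau > T)
    env[out] = 0.0
    envd[out] = 0.0
    return half_amp * s * env, half_amp * (sd * env + s * envd)


def _raised_cosine_step(tau: np.ndarray, width: float) -> np.ndarray:
    """Smooth 0 -> 1 transition over ``[0, width]``."""
    s = np.clip(tau / width, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * s))


def _raised_cosine_step_vr(tau: np.ndarray, width: float):
    s = np.clip(tau / width, 0.0, 1.0)
    val = 0.5 * (1.0 - np.cos(np.pi * s))
    rate = np.where((tau > 0) & (tau < width), 0.5 * np.pi / width * np.sin(np.pi * s), 0.0)
    return val, rate


def _random_mount(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _windowed(t, t0, t1, fn):
    """Evaluate ``fn(tau)`` on the window [t0, t1], zero elsewhere."""
    out = np.zeros_like(t)
    m = (t >= t0) & (t <= t1)
    out[m] = fn(t[m] - t0)
    return out


def _windowed_vr(t, t0, t1, fn):
    """Value and rate of a windowed trajectory segment."""
    val = np.zeros_like(t)
    rate = np.zeros_like(t)
    m = (t >= t0) & (t <= t1)
    val[m], rate[m] = fn(t[m] - t0)
    return val, rate


def _body_rates(orientation: Rotation, dt: float) -> np.ndarray:
    """Body angular rates by finite differencing on the rotation manifold.

    Uses a five-point (fourth-order) stencil on the body-frame rotation
    vectors relative to each sample, falling back to lower order near the
    ends.  The truncation error at typical sample rates is far below sensor
    noise floors.
    """
    n = len(orientation)
    gyro = np.empty((n, 3))

    def rel(i0, i1, j):
        """rotvec of sample (k + j) relative to sample k, for k in [i0, i1)."""
        return (orientation[i0:i1].inv() * orientation[i0 + j : i1 + j]).as_rotvec()

    if n >= 5:
        gyro[2:-2] = (
            -rel(2, n - 2, 2) + 8.0 * rel(2, n - 2, 1) - 8.0 * rel(2, n - 2, -1) + rel(2, n - 2, -2)
        ) / (12.0 * dt)
        for k in (1, n - 2):
            gyro[k] = (
                (orientation[k - 1].inv() * orientation[k + 1]).as_rotvec() / (2.0 * dt)
            )
    elif n >= 3:
        gyro[1:-1] = (orientation[:-2].inv() * orientation[2:]).as_rotvec() / (2.0 * dt)
    gyro[0] = (orientation[0].inv() * orientation[1]).as_rotvec() / dt
    gyro[-1] = (orientation[-2].inv() * orientation[-1]).as_rotvec() / dt
    return gyro


def imu_from_orientation(
    t,
    orientation: Rotation,
    heading_offset_deg: float = 0.0,
    drift_deg_s: float = 0.0,
    tilt_drift_deg_s: float = 0.0,
    gyro_noise_deg_s: float = 0.0,
    accel_noise_m_s2: float = 0.0,
    rng: np.random.Generator | None = None,
    with_mag: bool = False,
    lever_arm=None,
    body_rates=None,
    name: str = "",
):
    """Synthesize one IMU stream from a true orientation series.

    ``orientation`` is the link-mounted sensor's true orientation in the
    common world frame (active rotations, sensor -> world).  The reported
    quaternion is the true orientation composed with a world-frame error that
    is a heading rotation of ``heading_offset + drift * t`` degrees (plus an
    optional slow tilt component), emulating an independent, drifting
    world-frame estimate.  The noiseless gyro equals ``body_rates`` (rad/s)
    when the caller knows them analytically, otherwise it follows from
    finite differencing on the rotation manifold; accel is gravity in the
    sensor frame, plus lever-arm rotational terms when ``lever_arm`` is given.

    Returns ``(stream, heading_error_deg)``.
    """
    t = np.asarray(t, dtype=float)
    n = len(t)
    dts = np.diff(t)
    dt = float(np.mean(dts))
    if np.max(np.abs(dts - dt)) > 0.01 * dt:
        raise InvalidInputError("orientation series must be uniformly sampled")
    if rng is None:
        rng = np.random.default_rng(0)

    if body_rates is not None:
        gyro = np.array(body_rates, dtype=float)
    else:
        gyro = _body_rates(orientation, dt)

    accel = orientation.inv().apply(np.array([0.0, 0.0, GRAVITY]))
    if lever_arm is not None and np.linalg.norm(lever_arm) > 0:
        p = np.asarray(lever_arm, dtype=float)
        alpha = np.gradient(gyro, dt, axis=0)
        accel = accel + np.cross(alpha, p) + np.cross(gyro, np.cross(gyro, p))

    heading_err = heading_offset_deg + drift_deg_s * t
    err_rot = Rotation.from_euler("z", heading_err[:, None], degrees=True)
    if tilt_drift_deg_s:
        err_rot = err_rot * Rotation.from_euler("x", (tilt_drift_deg_s * t)[:, None], degrees=True)
    reported = err_rot * orientation
    quat = reported.as_quat(scalar_first=True)

    if gyro_noise_deg_s > 0:
        gyro = gyro + np.deg2rad(gyro_noise_deg_s) * rng.standard_normal((n, 3))
    if accel_noise_m_s2 > 0:
        accel = accel + accel_noise_m_s2 * rng.standard_normal((n, 3))
    mag = reported.inv().apply(np.array([1.0, 0.0, 0.0])) if with_mag else None

    stream = ImuStream(t, gyro, accel, mag, quat, name=name)
    return stream, heading_err


def generate_trial(spec: TrialSpec) -> SyntheticTrial:
    """Generate one synthetic recording (alignment sequence plus trial).

    Deterministic in ``spec`` (including ``spec.seed``): regenerating with the
    same spec yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    mount_s = (
        np.asarray(spec.mount_shank, dtype=float)
        if spec.mount_shank is not None
        else _random_mount(rng)
    )
    mount_t = (
        np.asarray(spec.mount_thigh, dtype=float)
        if spec.mount_thigh is not None
        else _random_mount(rng)
    )

    dt = 1.0 / spec.fs
    t_calib0 = spec.still_pre
    t_calib1 = t_calib0 + spec.calib_duration
    t_motion0 = t_calib1 + spec.still_mid
    t_motion1 = t_motion0 + spec.trial_duration
    total = t_motion1 + spec.still_post
    t = np.arange(0.0, total, dt)

    phases = {
        "still_pre": (0.0, t_calib0),
        "calibration": (t_calib0, t_calib1),
        "still_mid": (t_calib1, t_motion0),
        "motion": (t_motion0, t_motion1),
        "still_post": (t_motion1, total),
    }

    rom_fe, rom_ie, rom_aa = spec.roms
    hold = spec.trial_duration - 2.0 * spec.ramp
    if hold <= 0:
        raise InvalidInputError("trial_duration must exceed twice the tilt ramp")
    hold0 = t_motion0 + spec.ramp

    def traj(rom, k):
        if rom <= 0:
            return np.zeros_like(t), np.zeros_like(t)
        return _windowed_vr(t, hold0, hold0 + hold, lambda tau: _ramped_sin_vr(tau, hold, rom / 2.0, k))

    fe, fe_d = traj(rom_fe, spec.cycles[0])
    ie, ie_d = traj(rom_ie, spec.cycles[1])
    aa, aa_d = traj(rom_aa, spec.cycles[2])
    # hinge calibration movement is genuine joint flexion
    fe_cal, fe_cal_d = _windowed_vr(
        t, t_calib0, t_calib1,
        lambda tau: _ramped_sin_vr(tau, spec.calib_duration, spec.calib_rom_deg / 2.0, spec.calib_cycles),
    )
    fe, fe_d = fe + fe_cal, fe_d + fe_cal_d

    # whole-assembly (base) motion: FE split during hinge phases, wobble during
    # calibration, constant tilt held during the trial movement
    bx = -spec.fe_share * fe_cal
    bx_d = -spec.fe_share * fe_cal_d
    if spec.movement == "pure_FE":
        trial_fe, trial_fe_d = traj(rom_fe, spec.cycles[0])
        bx = bx - spec.fe_share * trial_fe
        bx_d = bx_d - spec.fe_share * trial_fe_d
    if spec.movement != "alignment" and spec.base_tilt_deg:
        m = (t >= t_motion0) & (t <= t_motion1)
        tau = t[m] - t_motion0
        up, up_d = _raised_cosine_step_vr(tau, spec.ramp)
        dn, dn_d = _raised_cosine_step_vr(tau - (spec.trial_duration - spec.ramp), spec.ramp)
        tilt = np.zeros_like(t)
        tilt_d = np.zeros_like(t)
        tilt[m] = spec.base_tilt_deg * (up - dn)
        tilt_d[m] = spec.base_tilt_deg * (up_d - dn_d)
        bx = bx + tilt
        bx_d = bx_d + tilt_d
    by, by_d = _windowed_vr(
        t, t_calib0, t_calib1,
        lambda tau: _ramped_sin_vr(tau, spec.calib_duration, spec.calib_wobble_deg[0] / 2.0,
                                   spec.calib_wobble_cycles[0]),
    )
    bz, bz_d = _windowed_vr(
        t, t_calib0, t_calib1,
        lambda tau: _ramped_sin_vr(tau, spec.calib_duration, spec.calib_wobble_deg[1] / 2.0,
                                   spec.calib_wobble_cycles[1]),
    )

    # orientation chains (base rotations applied about fixed world axes x, y, z
    # in that order; joint chain AA about Y, IE about Z, FE about X)
    rot_bx = Rotation.from_euler("x", bx[:, None], degrees=True)
    rot_by = Rotation.from_euler("y", by[:, None], degrees=True)
    rot_bz = Rotation.from_euler("z", bz[:, None], degrees=True)
    rot_aa = Rotation.from_euler("y", aa[:, None], degrees=True)
    rot_ie = Rotation.from_euler("z", ie[:, None], degrees=True)
    rot_fe = Rotation.from_euler("x", fe[:, None], degrees=True)
    r_base = rot_bz * rot_by * rot_bx
    r_rel = rot_aa * rot_ie * rot_fe
    r_shank_seg = r_base
    r_thigh_seg = r_base * r_rel

    # exact body rates via the composition rule w(P*Q) = Q^-1 w(P) + w(Q),
    # each single-axis factor contributing rate * axis in its own frame
    ex, ey, ez = np.eye(3)

    def col(rate_deg_s, axis):
        return np.deg2rad(rate_deg_s)[:, None] * axis

    w_base = rot_bx.inv().apply(rot_by.inv().apply(col(bz_d, ez)) + col(by_d, ey)) + col(bx_d, ex)
    w_rel = rot_fe.inv().apply(rot_ie.inv().apply(col(aa_d, ey)) + col(ie_d, ez)) + col(fe_d, ex)
    w_shank_seg = w_base
    w_thigh_seg = r_rel.inv().apply(w_base) + w_rel

    # mounts are DCMs sensor -> anatomical; as active rotations they carry
    # sensor coordinates into segment coordinates
    rot_mount_s = Rotation.from_matrix(mount_s)
    rot_mount_t = Rotation.from_matrix(mount_t)
    r_shank_sensor = r_shank_seg * rot_mount_s
    r_thigh_sensor = r_thigh_seg * rot_mount_t
    w_shank_sensor = rot_mount_s.inv().apply(w_shank_seg)
    w_thigh_sensor = rot_mount_t.inv().apply(w_thigh_seg)

    lever = np.array([0.0, 0.0, spec.lever_arm_m]) if spec.lever_arm_m else None
    shank, err_s = imu_from_orientation(
        t, r_shank_sensor,
        heading_offset_deg=0.0,
        drift_deg_s=spec.drift_shank_deg_s,
        tilt_drift_deg_s=spec.tilt_drift_deg_s[0],
        gyro_noise_deg_s=spec.gyro_noise_deg_s,
        accel_noise_m_s2=spec.accel_noise_m_s2,
        rng=rng, with_mag=spec.with_mag, lever_arm=lever,
        body_rates=w_shank_sensor, name="shank",
    )
    thigh, err_t = imu_from_orientation(
        t, r_thigh_sensor,
        heading_offset_deg=spec.heading_offset_deg,
        drift_deg_s=spec.drift_thigh_deg_s,
        tilt_drift_deg_s=spec.tilt_drift_deg_s[1],
        gyro_noise_deg_s=spec.gyro_noise_deg_s,
        accel_noise_m_s2=spec.accel_noise_m_s2,
        rng=rng, with_mag=spec.with_mag, lever_arm=lever,
        body_rates=w_thigh_sensor, name="thigh",
    )

    def truth_calib(mount, sensor_rot0, segment):
        x, y, z = mount[0], mount[1], mount[2]
        a0 = sensor_rot0.inv().apply(np.array([0.0, 0.0, GRAVITY]))
        return AnatomicalCalibration(x, x, y, z, mount, a0=a0, meta={"segment": segment})

    truth = JointAngleSeries(t, fe, ie, aa)
    return SyntheticTrial(
        spec=spec,
        t=t,
        truth=truth,
        shank=shank,
        thigh=thigh,
        calib_shank=truth_calib(mount_s, r_shank_sensor[0], "shank"),
        calib_thigh=truth_calib(mount_t, r_thigh_sensor[0], "thigh"),
        heading_error_shank_deg=err_s,
        heading_error_thigh_deg=err_t,
        phases=phases,
    )
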