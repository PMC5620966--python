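"""Core 3D rotation machinery.

Conventions
-----------
* Quaternions are Hamilton, scalar-first ``(w, x, y, z)``, canonicalized to
  ``w >= 0``.  ``q`` and ``-q`` encode the same rotation.
* A direction cosine matrix (DCM) ``R_B_A`` transforms coordinates from frame
  A to frame B: ``v_B = R_B_A @ v_A``.  Its rows are the B-frame axes
  expressed in A.  Equivalently it is the matrix of the *active* rotation that
  carries the B axes onto the A axes, so for a sensor with orientation
  quaternion ``q`` (sensor -> its world frame), ``quat_to_dcm(q)`` is the DCM
  from sensor coordinates to world coordinates.
* Internal angles are radians; public joint-angle interfaces use degrees.

Anatomical Euler sequences
--------------------------
Anatomical axes map to frame axes as X = medial-lateral (FE axis),
Y = anterior-posterior (AA axis), Z = superior-inferior (IE axis).  A
decomposition sequence is an ordered triple of the labels ``"FE"``, ``"IE"``,
``"AA"``; the knee-analog mechanism order is AA first, IE second, FE third,
while the ISB recommendation is the reverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, InvalidInputError

__all__ = [
    "KNEE_SEQUENCE",
    "ISB_SEQUENCE",
    "AxisAngle",
    "quat_canonical",
    "quat_to_dcm",
    "dcm_to_quat",
    "axis_angle_between",
    "skew",
    "rodrigues",
    "compose_euler",
    "decompose_dcm",
    "estimate_orientation",
]

#: label -> frame axis of the anatomical coordinate system
AXIS_OF_LABEL = {"FE": "X", "IE": "Z", "AA": "Y"}

#: decomposition order of the serial knee-analog mechanism (AA, then IE, then FE)
KNEE_SEQUENCE = ("AA", "IE", "FE")

#: ISB-recommended order (FE first, IE second, AA third)
ISB_SEQUENCE = ("FE", "IE", "AA")

_DCM_TOL = 1e-10


def _as_finite(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite components")
    return arr


def seq_to_scipy(seq) -> str:
    """Map an anatomical label triple to a scipy intrinsic Euler string."""
    labels = tuple(seq)
    if sorted(labels) != sorted(AXIS_OF_LABEL):
        raise InvalidInputError(f"sequence must be a permutation of FE/IE/AA, got {labels}")
    return "".join(AXIS_OF_LABEL[lbl] for lbl in labels)


def quat_canonical(q) -> np.ndarray:
    """Normalize a scalar-first quaternion (or batch) and flip so ``w >= 0``."""
    q = _as_finite(q, "quaternion")
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise InvalidInputError("zero-norm quaternion")
    q = q / norm
    flip = np.where(q[..., :1] < 0.0, -1.0, 1.0)
    return q * flip


def quat_to_dcm(q) -> np.ndarray:
    """Convert scalar-first unit quaternion(s) to DCM(s).

    For an orientation quaternion sensor -> world, the result is ``R_W_S``
    (world coordinates of a sensor-frame vector via ``R @ v``).
    """
    q = quat_canonical(q)
    return Rotation.from_quat(q, scalar_first=True).as_matrix()


def dcm_to_quat(R) -> np.ndarray:
    """Inverse of :func:`quat_to_dcm`; returns the canonical (w >= 0) quaternion."""
    R = _as_finite(R, "DCM")
    return quat_canonical(Rotation.from_matrix(R).as_quat(scalar_first=True))


@dataclass(frozen=True)
class AxisAngle:
    """Rotation axis ``k`` (unit 3-vector), angle ``theta`` in [0, pi] radians.

    ``defined`` is False when the axis is arbitrary because the angle is
    (numerically) zero; callers should then substitute the identity rotation.
    """

    axis: np.ndarray
    angle: float
    defined: bool = True

    def __post_init__(self):
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))

    @property
    def skew(self) -> np.ndarray:
        """Skew-symmetric (cross-product) matrix of the axis."""
        return skew(self.axis)


def skew(v) -> np.ndarray:
    """Skew-symmetric matrix ``[v]x`` such that ``[v]x @ u = v x u``."""
    v = _as_finite(v, "vector")
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


def axis_angle_between(u, v, parallel_tol: float = 1e-8) -> AxisAngle:
    """Axis and angle of the minimal rotation carrying unit vector ``u`` onto ``v``.

    The axis is ``u x v`` normalized and the angle ``arccos(u . v)`` (dot
    clamped to [-1, 1]).  Nearly parallel inputs (``|u x v| < parallel_tol``)
    return an ``AxisAngle`` flagged ``defined=False`` with the tiny residual
    angle, which callers treat as the identity.  Antiparallel inputs raise
    :class:`DegenerateGeometryError`: a 180 deg world-frame disagreement
    indicates calibration failure, not drift, and has no preferred axis.
    """
    u = _as_finite(u, "u")
    v = _as_finite(v, "v")
    for name, w in (("u", u), ("v", v)):
        if abs(np.linalg.norm(w) - 1.0) > 1e-6:
            raise InvalidInputError(f"{name} is not a unit vector")
    c = np.cross(u, v)
    d = float(np.clip(np.dot(u, v), -1.0, 1.0))
    theta = float(np.arccos(d))
    nc = float(np.linalg.norm(c))
    if nc < parallel_tol:
        if d < 0.0:
            raise DegenerateGeometryError("antiparallel vectors: rotation axis undefined")
        return AxisAngle(np.array([1.0, 0.0, 0.0]), theta, defined=False)
    return AxisAngle(c / nc, theta)


def rodrigues(aa, angle: float | None = None) -> np.ndarray:
    """Rotation matrix from Rodrigues' formula.

    ``C = I + sin(theta) K + (1 - cos(theta)) K^2`` with ``K`` the
    skew-symmetric matrix of the unit axis.  Accepts an :class:`AxisAngle`
    or an ``(axis, angle)`` pair.  An undefined axis (angle ~ 0) yields the
    identity.
    """
    if isinstance(aa, AxisAngle):
        axis, theta, defined = aa.axis, aa.angle, aa.defined
    else:
        axis, theta, defined = np.asarray(aa, dtype=float), float(angle), True
    if not defined:
        return np.eye(3)
    axis = _as_finite(axis, "axis")
    n = np.linalg.norm(axis)
    if abs(n - 1.0) > 1e-6:
        raise InvalidInputError("rotation axis must be a unit vector")
    K = skew(axis / n)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def compose_euler(angles, seq=KNEE_SEQUENCE, degrees: bool = False) -> np.ndarray:
    """Compose a relative-orientation DCM from three anatomical angles.

    ``angles`` are given in ``seq`` order (e.g. ``(aa, ie, fe)`` for the knee
    sequence) and describe successive rotations carrying the source
    (shank-anatomical) frame onto the target (thigh-anatomical) frame, each
    about the current anatomical axis.  Returns the DCM ``R_AT_AS`` (source ->
    target coordinate transform); batched input ``(N, 3)`` gives ``(N, 3, 3)``.
    """
    angles = _as_finite(angles, "angles")
    r = Rotation.from_euler(seq_to_scipy(seq), angles, degrees=degrees)
    return r.inv().as_matrix()


def decompose_dcm(R, seq=KNEE_SEQUENCE, degrees: bool = False, return_flags: bool = False):
    """Ordered Euler decomposition of relative-orientation DCM(s).

    Inverse of :func:`compose_euler`.  The middle angle is confined to its
    principal range [-90 deg, 90 deg].  At gimbal lock (middle angle within
    ~1e-8 of +/-90 deg) the third angle is set to zero by convention, the
    remaining rotation folded into the first angle, and the sample flagged
    when ``return_flags`` is requested.
    """
    R = _as_finite(R, "DCM")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        angles = Rotation.from_matrix(R).inv().as_euler(seq_to_scipy(seq), degrees=degrees)
    if not return_flags:
        return angles
    quarter = 90.0 if degrees else np.pi / 2
    flags = np.abs(np.abs(np.atleast_2d(angles)[..., 1]) - quarter) < 1e-8
    if angles.ndim == 1:
        flags = bool(flags[0])
    return angles, flags


def estimate_orientation(
    t,
    gyro,
    accel=None,
    mag=None,
    q0=None,
    acc_gain: float = 0.0,
    mag_gain: float = 0.0,
    dt_tol: float = 0.01,
) -> np.ndarray:
    """Strapdown orientation filter: gyro integration with optional corrections.

    A minimal complementary filter: the body rate is integrated sample by
    sample (exact for piecewise-constant rate); when ``acc_gain > 0`` the tilt
    estimate is nudged toward the measured gravity direction, and when
    ``mag_gain > 0`` the heading toward the measured horizontal field
    direction.  With both gains zero, heading drift accumulates at the gyro
    bias rate, which is the phenomenology the hinge correction removes.

    Parameters
    ----------
    t : (N,) seconds, uniformly sampled (within ``dt_tol`` relative).
    gyro : (N, 3) rad/s in the sensor frame.
    accel : (N, 3) m/s^2, needed when ``acc_gain > 0``.
    mag : (N, 3) arbitrary units, needed when ``mag_gain > 0``.
    q0 : initial scalar-first quaternion (sensor -> world), default identity.

    Returns
    -------
    (N, 4) scalar-first unit quaternions, ``w >= 0``.
    """
    t = _as_finite(t, "t")
    gyro = _as_finite(gyro, "gyro")
    n = len(t)
    if n < 2:
        raise InvalidInputError("need at least two samples")
    dts = np.diff(t)
    dt = float(np.mean(dts))
    if dt <= 0 or np.max(np.abs(dts - dt)) > dt_tol * dt:
        raise InvalidInputError("timestamps not uniform within tolerance")
    if q0 is None:
        r = Rotation.identity()
    else:
        r = Rotation.from_quat(quat_canonical(q0), scalar_first=True)

    out = np.empty((n, 4))
    out[0] = r.as_quat(scalar_first=True)
    up = np.array([0.0, 0.0, 1.0])
    north = np.array([1.0, 0.0, 0.0])
    for k in range(1, n):
        # trapezoidal body-rate sample over the step
        r = r * Rotation.from_rotvec(0.5 * (gyro[k - 1] + gyro[k]) * dt)
        if acc_gain > 0.0 and accel is not None:
            a = accel[k]
            na = np.linalg.norm(a)
            if na > 1e-9:
                up_meas = a / na  # gravity direction in sensor frame
                up_est = r.inv().apply(up)
                corr = np.cross(up_meas, up_est)
                r = r * Rotation.from_rotvec(acc_gain * dt * corr)
        if mag_gain > 0.0 and mag is not None:
            m_world = r.apply(mag[k])
            m_world[2] = 0.0
            nm = np.linalg.norm(m_world)
            if nm > 1e-9:
                err = np.cross(m_world / nm, north)  # vertical-axis heading error
                r = r * Rotation.from_rotvec(r.inv().apply(mag_gain * dt * err))
        out[k] = r.as_quat(scalar_first=True)
    return quat_canonical(out)
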