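"""World-frame correction from the hinge constraint.

The two IMUs maintain independent world frames that are misaligned (distinct
heading references) and drift apart over time.  While the knee functions as a
hinge, the medial-lateral axis must be one common direction, so expressing
each segment's hinge axis in its own world frame,

    u(t) = R_WS_S(t) n_S,      v(t) = R_WT_T(t) n_T,

the correction DCM ``C(t)`` (shank-world -> thigh-world) is the minimal
rotation aligning ``u`` onto ``v``: axis ``u x v`` normalized, angle
``arccos(u . v)``, matrix by Rodrigues' formula.  Between hinge intervals the
correction is interpolated on the rotation manifold (spherical-linear in the
quaternion, which for coaxial anchors reduces to linear interpolation of the
angle); outside the first/last anchor the nearest anchor is held.

The corrected relative orientation of the anatomical frames is the chain

    R_ATAS(t) = R_AT_T . R_T_WT(t) . C(t) . R_WS_S(t) . R_S_AS

whose ordered Euler decomposition yields the FE/IE/AA knee angles.  Setting
``C = I`` gives the uncorrected estimate for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .errors import GridMismatchError, InvalidInputError, NoAnchorError
from .rotations import KNEE_SEQUENCE, axis_angle_between, decompose_dcm, rodrigues
from .streams import JointAngleSeries

__all__ = [
    "CorrectionTimeline",
    "correction_at_sample",
    "anchor_corrections",
    "build_timeline",
    "relative_orientation",
    "knee_angles",
    "yaw_vertical",
]


def correction_at_sample(R_ws_s, R_wt_t, n_s, n_t) -> np.ndarray:
    """Correction DCM at one hinge sample.

    Satisfies ``C @ (R_ws_s @ n_s) == R_wt_t @ n_t`` to numerical precision.
    Antiparallel world-frame hinge axes raise ``DegenerateGeometryError``
    (batch construction skips such anchors with a warning instead).
    """
    u = np.asarray(R_ws_s, float) @ np.asarray(n_s, float)
    v = np.asarray(R_wt_t, float) @ np.asarray(n_t, float)
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    return rodrigues(axis_angle_between(u, v))


def anchor_corrections(
    rot_ws_s: Rotation,
    rot_wt_t: Rotation,
    n_s,
    n_t,
    mask,
    t,
):
    """Vectorized correction rotations at every sample flagged in ``mask``.

    Returns ``(anchor_times, anchor_rotations, n_skipped)``; antiparallel
    samples (world frames disagreeing by ~180 deg, i.e. calibration failure
    rather than drift) are skipped with a warning.
    """
    t = np.asarray(t, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return t[:0], Rotation.identity(0), 0
    n_s = np.asarray(n_s, float) / np.linalg.norm(n_s)
    n_t = np.asarray(n_t, float) / np.linalg.norm(n_t)
    u = rot_ws_s[idx].apply(n_s)
    v = rot_wt_t[idx].apply(n_t)
    c = np.cross(u, v)
    d = np.clip(np.sum(u * v, axis=1), -1.0, 1.0)
    theta = np.arccos(d)
    nc = np.linalg.norm(c, axis=1)

    anti = (nc < 1e-12) & (d < 0.0)
    if anti.any():
        warnings.warn(
            f"skipping {int(anti.sum())} anchors with antiparallel world-frame hinge axes",
            RuntimeWarning,
            stacklevel=2,
        )
    tiny = (nc < 1e-12) & ~anti
    keep = ~anti
    rotvec = np.zeros((idx.size, 3))
    ok = ~tiny & ~anti
    rotvec[ok] = c[ok] / nc[ok, None] * theta[ok, None]
    return t[idx[keep]], Rotation.from_rotvec(rotvec[keep]), int(anti.sum())


@dataclass
class CorrectionTimeline:
    """Correction rotations at hinge anchors and interpolated on the full grid."""

    anchor_times: np.ndarray
    anchor_rotations: Rotation
    t: np.ndarray
    series: Rotation  # correction at every grid sample

    @property
    def matrices(self) -> np.ndarray:
        return self.series.as_matrix()

    @property
    def anchor_axis_angle(self):
        """(axis, angle_rad) arrays of the per-anchor corrections."""
        rv = self.anchor_rotations.as_rotvec()
        ang = np.linalg.norm(rv, axis=-1)
        axis = np.divide(rv, ang[..., None], out=np.zeros_like(np.atleast_2d(rv)),
                         where=ang[..., None] > 1e-12)
        return axis, ang

    @property
    def equivalent_angle_deg(self) -> np.ndarray:
        """Magnitude of the interpolated correction per sample, degrees."""
        return np.degrees(np.linalg.norm(self.series.as_rotvec(), axis=-1))


def build_timeline(
    anchor_times,
    anchor_rotations: Rotation,
    grid_t,
    smooth_window: float = 0.0,
) -> CorrectionTimeline:
    """Interpolate anchor corrections onto the full time grid.

    Inside update intervals the per-sample anchors are reproduced exactly
    (anchors are grid samples); across Case-2 gaps the correction follows the
    geodesic between the bounding anchors; before the first and after the
    last anchor the nearest anchor is held (there is no basis for
    extrapolating drift).  ``smooth_window`` (seconds) optionally applies a
    moving-average low-pass to the anchor rotation vectors first.
    """
    anchor_times = np.asarray(anchor_times, dtype=float)
    grid_t = np.asarray(grid_t, dtype=float)
    n = len(anchor_times)
    if n == 0:
        raise NoAnchorError("cannot build a correction timeline without anchors")
    if smooth_window > 0.0 and n > 2:
        from scipy.ndimage import uniform_filter1d

        dt = np.median(np.diff(anchor_times)) if n > 1 else smooth_window
        size = max(1, int(round(smooth_window / max(dt, 1e-9))))
        rv = uniform_filter1d(anchor_rotations.as_rotvec(), size=size, axis=0, mode="nearest")
        anchor_rotations = Rotation.from_rotvec(rv)
    if n == 1:
        series = Rotation.from_rotvec(
            np.broadcast_to(anchor_rotations.as_rotvec().reshape(1, 3), (len(grid_t), 3)).copy()
        )
        return CorrectionTimeline(anchor_times, anchor_rotations, grid_t, series)
    sl = Slerp(anchor_times, anchor_rotations)
    series = sl(np.clip(grid_t, anchor_times[0], anchor_times[-1]))
    return CorrectionTimeline(anchor_times, anchor_rotations, grid_t, series)


def relative_orientation(
    R_at_t,
    rot_wt_t: Rotation,
    correction,
    rot_ws_s: Rotation,
    R_as_s,
) -> np.ndarray:
    """Per-sample corrected relative-orientation DCMs ``R_ATAS`` (N, 3, 3).

    ``correction`` may be a :class:`CorrectionTimeline`, a Rotation series,
    an (N, 3, 3) array, or None for the uncorrected chain.
    """
    M_wt = rot_wt_t.as_matrix()
    M_ws = rot_ws_s.as_matrix()
    if M_wt.shape != M_ws.shape:
        raise GridMismatchError("orientation series lengths differ")
    n = M_ws.shape[0]
    if correction is None:
        C = np.broadcast_to(np.eye(3), (n, 3, 3))
    elif isinstance(correction, CorrectionTimeline):
        C = correction.matrices
    elif isinstance(correction, Rotation):
        C = correction.as_matrix()
    else:
        C = np.asarray(correction, dtype=float)
    if C.shape != (n, 3, 3):
        raise GridMismatchError("correction series does not match the time grid")
    A = np.asarray(R_at_t, dtype=float)  # thigh sensor -> thigh anatomical
    B = np.asarray(R_as_s, dtype=float).T  # shank anatomical -> shank sensor
    inner = np.einsum("nji,njk,nkl->nil", M_wt, C, M_ws)  # R_T_WT . C . R_WS_S
    return np.einsum("ij,njk,kl->nil", A, inner, B)


def knee_angles(rel, t, seq=KNEE_SEQUENCE) -> JointAngleSeries:
    """Decompose relative-orientation DCMs into FE/IE/AA angles, degrees.

    ``seq`` is the decomposition order (default: the knee-analog mechanism
    order AA -> IE -> FE; pass ``ISB_SEQUENCE`` for the ISB recommendation).
    Gimbal-locked samples keep the scipy convention (third angle zeroed) and
    are recorded on the returned series as ``.gimbal_flags``.
    """
    rel = np.asarray(rel, dtype=float)
    angles, flags = decompose_dcm(rel, seq=seq, degrees=True, return_flags=True)
    angles = np.atleast_2d(angles)
    by_label = {lbl: angles[:, i] for i, lbl in enumerate(seq)}
    out = JointAngleSeries(np.asarray(t, float), by_label["FE"], by_label["IE"], by_label["AA"])
    out.gimbal_flags = np.atleast_1d(flags)
    return out


def yaw_vertical(rot_ws_s: Rotation):
    """Yaw and vertical (elevation) diagnostic angles of a sensor frame.

    For each sample, the sensor x-axis is expressed in the world frame; the
    yaw ``psi`` is the angle between the world x-axis and the horizontal
    projection of the sensor x-axis, in (-180, 180] degrees, and ``phi`` is
    its elevation out of the horizontal plane, in [-90, 90] degrees.  Returns
    ``(psi_deg, phi_deg, undefined)`` where ``undefined`` flags samples with
    the sensor x-axis within ~1e-6 of vertical (yaw indeterminate).

    Slow trends in ``psi`` visualize heading drift of the on-board estimate.
    """
    x_world = rot_ws_s.as_matrix()[..., :, 0]
    x_world = np.atleast_2d(x_world)
    phi = np.degrees(np.arcsin(np.clip(x_world[:, 2], -1.0, 1.0)))
    horiz = np.hypot(x_world[:, 0], x_world[:, 1])
    undefined = horiz < 1e-6
    psi = np.degrees(np.arctan2(x_world[:, 1], x_world[:, 0]))
    psi[undefined] = 0.0
    return psi, phi, undefined
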