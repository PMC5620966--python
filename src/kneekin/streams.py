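"""Time-series containers: IMU streams, time intervals, CSV interchange.

The on-disk format is a plain CSV with columns ``t_s, gx_rad_s, gy_rad_s,
gz_rad_s, ax_m_s2, ay_m_s2, az_m_s2`` plus optional ``mx, my, mz`` and
``qw, qx, qy, qz`` (scalar-first orientation of the sensor frame in that
sensor's own world frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import GridMismatchError, InvalidInputError
from .rotations import quat_canonical, quat_to_dcm

GRAVITY = 9.81  # m/s^2

_GYRO_COLS = ["gx_rad_s", "gy_rad_s", "gz_rad_s"]
_ACC_COLS = ["ax_m_s2", "ay_m_s2", "az_m_s2"]
_MAG_COLS = ["mx", "my", "mz"]
_QUAT_COLS = ["qw", "qx", "qy", "qz"]


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, non-overlapping half-open time intervals ``[start, end)`` in seconds."""

    intervals: tuple = ()

    def __post_init__(self):
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        for a, b in ivs:
            if not b > a:
                raise InvalidInputError(f"empty or inverted interval ({a}, {b})")
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise InvalidInputError("intervals overlap or are unsorted")
        object.__setattr__(self, "intervals", ivs)

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __bool__(self):
        return bool(self.intervals)

    @property
    def duration(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def mask(self, t) -> np.ndarray:
        """Boolean array marking samples of ``t`` inside any interval."""
        t = np.asarray(t, dtype=float)
        m = np.zeros(t.shape, dtype=bool)
        for a, b in self.intervals:
            m |= (t >= a) & (t < b)
        return m

    @classmethod
    def from_mask(cls, t, mask) -> "IntervalSet":
        """Maximal contiguous True runs of ``mask`` as intervals on grid ``t``.

        The interval end is the time of the sample following the run (half-open),
        or the last time plus one sample period for a run reaching the end.
        """
        t = np.asarray(t, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if t.shape != mask.shape:
            raise GridMismatchError("t and mask lengths differ")
        if not mask.any():
            return cls(())
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        starts, ends = edges[::2], edges[1::2]
        out = []
        for s, e in zip(starts, ends):
            end_t = t[e] if e < len(t) else t[-1] + dt
            out.append((t[s], end_t))
        return cls(tuple(out))


def _uniform_dt(t, tol=0.01) -> float:
    dts = np.diff(t)
    dt = float(np.mean(dts))
    if dt <= 0 or np.max(np.abs(dts - dt)) > tol * dt:
        raise InvalidInputError("timestamps not uniform within tolerance")
    return dt


@dataclass
class ImuStream:
    """Time-synchronized samples from one IMU.

    Attributes
    ----------
    t : (N,) seconds, strictly increasing.
    gyro : (N, 3) angular rate, rad/s, sensor frame.
    accel : (N, 3) specific force, m/s^2, sensor frame (reads ``+g`` upward at rest).
    mag : optional (N, 3) normalized magnetic field, sensor frame.
    quat : optional (N, 4) scalar-first orientation of the sensor frame in this
        sensor's own world frame (the on-board filter output).
    """

    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    mag: np.ndarray | None = None
    quat: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        n = len(self.t)
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise InvalidInputError("gyro/accel must be (N, 3) matching t")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
            if self.mag.shape != (n, 3):
                raise InvalidInputError("mag must be (N, 3)")
        if self.quat is not None:
            self.quat = quat_canonical(np.asarray(self.quat, dtype=float))
            if self.quat.shape != (n, 4):
                raise InvalidInputError("quat must be (N, 4)")

    def __len__(self):
        return len(self.t)

    @property
    def fs(self) -> float:
        """Sample rate in Hz (requires a uniform grid)."""
        return 1.0 / _uniform_dt(self.t)

    def world_dcms(self) -> np.ndarray:
        """(N, 3, 3) DCMs sensor -> own world frame from the quaternion channel."""
        if self.quat is None:
            raise InvalidInputError(f"stream {self.name!r} carries no orientation quaternions")
        return quat_to_dcm(self.quat)

    def world_rotations(self) -> Rotation:
        if self.quat is None:
            raise InvalidInputError(f"stream {self.name!r} carries no orientation quaternions")
        return Rotation.from_quat(self.quat, scalar_first=True)

    def slice(self, interval) -> "ImuStream":
        """Sub-stream over ``[start, end)``."""
        a, b = interval
        m = (self.t >= a) & (self.t < b)
        return ImuStream(
            self.t[m],
            self.gyro[m],
            self.accel[m],
            None if self.mag is None else self.mag[m],
            None if self.quat is None else self.quat[m],
            self.name,
        )

    def shift_time(self, lag: float) -> "ImuStream":
        """Return a copy with ``lag`` seconds added to every timestamp."""
        return ImuStream(self.t + lag, self.gyro, self.accel, self.mag, self.quat, self.name)

    def resample(self, new_t) -> "ImuStream":
        """Linear interpolation of all channels onto ``new_t`` (slerp for quaternions)."""
        new_t = np.asarray(new_t, dtype=float)

        def interp_cols(x):
            return np.column_stack([np.interp(new_t, self.t, x[:, i]) for i in range(3)])

        quat = None
        if self.quat is not None:
            from scipy.spatial.transform import Slerp

            sl = Slerp(self.t, Rotation.from_quat(self.quat, scalar_first=True))
            tq = np.clip(new_t, self.t[0], self.t[-1])
            quat = quat_canonical(sl(tq).as_quat(scalar_first=True))
        return ImuStream(
            new_t,
            interp_cols(self.gyro),
            interp_cols(self.accel),
            None if self.mag is None else interp_cols(self.mag),
            quat,
            self.name,
        )

    # -- CSV interchange ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        data = {"t_s": self.t}
        data.update({c: self.gyro[:, i] for i, c in enumerate(_GYRO_COLS)})
        data.update({c: self.accel[:, i] for i, c in enumerate(_ACC_COLS)})
        if self.mag is not None:
            data.update({c: self.mag[:, i] for i, c in enumerate(_MAG_COLS)})
        if self.quat is not None:
            data.update({c: self.quat[:, i] for i, c in enumerate(_QUAT_COLS)})
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ImuStream":
        df = pd.read_csv(path)
        required = ["t_s", *_GYRO_COLS, *_ACC_COLS]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InvalidInputError(f"IMU CSV missing columns: {missing}")
        mag = df[_MAG_COLS].to_numpy() if all(c in df.columns for c in _MAG_COLS) else None
        quat = df[_QUAT_COLS].to_numpy() if all(c in df.columns for c in _QUAT_COLS) else None
        return cls(
            df["t_s"].to_numpy(),
            df[_GYRO_COLS].to_numpy(),
            df[_ACC_COLS].to_numpy(),
            mag,
            quat,
            name=Path(path).stem,
        )


@dataclass
class JointAngleSeries:
    """FE/IE/AA knee angles over time, degrees."""

    t: np.ndarray
    fe: np.ndarray
    ie: np.ndarray
    aa: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for name in ("fe", "ie", "aa"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise GridMismatchError(f"{name} length differs from t")
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    def __len__(self):
        return len(self.t)

    @property
    def angles(self) -> np.ndarray:
        """(N, 3) array in FE, IE, AA column order, degrees."""
        return np.column_stack([self.fe, self.ie, self.aa])

    def axis(self, name: str) -> np.ndarray:
        return {"FE": self.fe, "IE": self.ie, "AA": self.aa}[name]

    def slice(self, interval) -> "JointAngleSeries":
        a, b = interval
        m = (self.t >= a) & (self.t < b)
        return JointAngleSeries(self.t[m], self.fe[m], self.ie[m], self.aa[m])

    def resample(self, new_t) -> "JointAngleSeries":
        new_t = np.asarray(new_t, dtype=float)
        return JointAngleSeries(
            new_t,
            np.interp(new_t, self.t, self.fe),
            np.interp(new_t, self.t, self.ie),
            np.interp(new_t, self.t, self.aa),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "fe_deg": self.fe, "ie_deg": self.ie, "aa_deg": self.aa}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "JointAngleSeries":
        df = pd.read_csv(path)
        return cls(
            df["t_s"].to_numpy(),
            df["fe_deg"].to_numpy(),
            df["ie_deg"].to_numpy(),
            df["aa_deg"].to_numpy(),
        )
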