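"""Quantitative comparison of estimated vs. truth joint angles.

Per axis: range of motion of the truth (max - min), RMS error, Pearson r,
and the slope / y-intercept of the ordinary least-squares fit of the
estimate on the truth (truth as abscissa), plus the RMS error relative to
the ROM in percent.  Axes whose truth has no variance (not exercised in a
trial) get the correlation and fit flagged undefined.

Pooling across trials concatenates samples (not per-trial metric averages),
matching a pooled-session treatment: for equal-length trials the pooled RMS
is the quadratic mean of the per-trial RMS values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import GridMismatchError
from .streams import JointAngleSeries

__all__ = ["AxisMetrics", "ValidationReport", "compare", "compare_arrays", "batch_validate"]

AXES = ("FE", "IE", "AA")


@dataclass(frozen=True)
class AxisMetrics:
    """Comparison metrics for one anatomical angle (degrees where dimensional)."""

    axis: str
    n: int
    rom: float
    rms: float
    r: float
    slope: float
    intercept: float
    rel_rms: float  # RMS as percent of ROM
    r_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "axis": self.axis, "n": self.n, "rom_deg": self.rom, "rms_deg": self.rms,
            "r": self.r, "slope": self.slope, "intercept_deg": self.intercept,
            "rel_rms_pct": self.rel_rms, "r_defined": self.r_defined,
        }


@dataclass
class ValidationReport:
    """Per-axis metrics for one trial or one pooled set of trials."""

    metrics: dict  # axis label -> AxisMetrics
    n_samples: int = 0

    def __getitem__(self, axis: str) -> AxisMetrics:
        return self.metrics[axis]

    def max_rms(self) -> float:
        return max(m.rms for m in self.metrics.values())

    def min_r(self) -> float:
        defined = [m.r for m in self.metrics.values() if m.r_defined]
        return min(defined) if defined else float("nan")

    def as_dict(self) -> dict:
        return {axis: m.as_dict() for axis, m in self.metrics.items()}

    def to_table(self) -> str:
        head = f"{'axis':<4} {'ROM':>8} {'RMS':>8} {'r':>7} {'slope':>7} {'b':>8} {'RMS%':>7}"
        rows = [head]
        for axis in AXES:
            if axis not in self.metrics:
                continue
            m = self.metrics[axis]
            r = f"{m.r:7.3f}" if m.r_defined else "      —"
            slope = f"{m.slope:7.3f}" if m.r_defined else "      —"
            b = f"{m.intercept:8.3f}" if m.r_defined else "       —"
            rel = f"{m.rel_rms:7.2f}" if np.isfinite(m.rel_rms) else "      —"
            rows.append(f"{axis:<4} {m.rom:8.2f} {m.rms:8.3f} {r} {slope} {b} {rel}")
        return "\n".join(rows)


def compare_arrays(est: np.ndarray, truth: np.ndarray, axis: str = "") -> AxisMetrics:
    """Metrics for one angle series pair on a common grid."""
    est = np.asarray(est, float)
    truth = np.asarray(truth, float)
    if est.shape != truth.shape:
        raise GridMismatchError("estimate and truth lengths differ")
    n = est.size
    rom = float(truth.max() - truth.min()) if n else float("nan")
    rms = float(np.sqrt(np.mean((est - truth) ** 2)))
    if np.std(truth) < 1e-12:
        return AxisMetrics(axis, n, rom, rms, float("nan"), float("nan"), float("nan"),
                           float("nan"), r_defined=False)
    fit = stats.linregress(truth, est)
    rel = rms / rom * 100.0 if rom > 0 else float("nan")
    return AxisMetrics(axis, n, rom, rms, float(fit.rvalue), float(fit.slope),
                       float(fit.intercept), rel)


def compare(est: JointAngleSeries, truth: JointAngleSeries) -> ValidationReport:
    """Per-axis comparison; the truth is resampled onto the estimate grid if needed."""
    if len(truth) != len(est) or not np.allclose(truth.t, est.t, atol=1e-9):
        truth = truth.resample(est.t)
    metrics = {axis: compare_arrays(est.axis(axis), truth.axis(axis), axis) for axis in AXES}
    return ValidationReport(metrics, n_samples=len(est))


def batch_validate(pairs) -> tuple:
    """Pooled metrics over ``(est, truth)`` pairs plus the per-trial reports.

    Samples are concatenated per axis across trials before computing the
    metrics, so long trials weigh proportionally more, as in a pooled-session
    analysis.  Returns ``(pooled_report, [per_trial_reports])``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("batch_validate needs at least one trial")
    per_trial = []
    pooled_est = {axis: [] for axis in AXES}
    pooled_truth = {axis: [] for axis in AXES}
    for est, truth in pairs:
        if len(truth) != len(est) or not np.allclose(truth.t, est.t, atol=1e-9):
            truth = truth.resample(est.t)
        per_trial.append(compare(est, truth))
        for axis in AXES:
            pooled_est[axis].append(est.axis(axis))
            pooled_truth[axis].append(truth.axis(axis))
    metrics = {
        axis: compare_arrays(
            np.concatenate(pooled_est[axis]), np.concatenate(pooled_truth[axis]), axis
        )
        for axis in AXES
    }
    n = sum(len(e) for e, _ in pairs)
    return ValidationReport(metrics, n_samples=n), per_trial
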