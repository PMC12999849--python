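"""Kinematic evaluation statistics.

Elbow trajectories are projected onto the plane perpendicular to the
initial humerus orientation and summarized with polar ensemble statistics:
per-timestep mean displacement magnitude with circular-mean direction,
1-SD covariance ellipses of displacement scatter, and peak displacement /
time-to-peak by two methods (peak of the ensemble-average trace, and the
mean +/- SD of the per-trace peaks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class EvaluationError(ValueError):
    pass


@dataclass
class PlanarTrace:
    """2D elbow displacement in the evaluation plane (mm) on a time grid (s)."""

    time: np.ndarray
    xy: np.ndarray           # (n, 2), mm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(len(self.time), 2)

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.xy, axis=1)

    @property
    def direction(self) -> np.ndarray:
        return np.arctan2(self.xy[:, 1], self.xy[:, 0])

    def resampled(self, grid: np.ndarray) -> "PlanarTrace":
        xy = np.column_stack([
            np.interp(grid, self.time, self.xy[:, 0]),
            np.interp(grid, self.time, self.xy[:, 1]),
        ])
        return PlanarTrace(grid, xy)


@dataclass
class EllipseStats:
    """1-SD covariance ellipse: semi-axes are the square roots of the
    eigenvalues of the 2x2 sample covariance."""

    center: np.ndarray
    semi_axes: tuple[float, float]   # (a, b), a >= b
    orientation: float               # rad, major-axis angle from +x

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]


@dataclass
class PeakStats:
    method: str              # "peak_of_average" | "average_of_peaks"
    peak: float              # mm
    ttp: float               # s
    peak_sd: float | None = None
    ttp_sd: float | None = None


def project_to_plane(trajectory: np.ndarray, humerus_axis: np.ndarray,
                     origin: np.ndarray | None = None,
                     time: np.ndarray | None = None,
                     lateral_hint: np.ndarray = np.array([0.0, 1.0, 0.0])
                     ) -> PlanarTrace:
    """Project a 3D elbow trajectory (m) onto the plane perpendicular to the
    initial humerus axis; output displacement (mm) relative to the first
    sample, in (Y lateral, Z) plane coordinates."""
    traj = np.asarray(trajectory, dtype=float).reshape(-1, 3)
    axis = np.asarray(humerus_axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise EvaluationError("humerus axis must be non-zero")
    axis = axis / n
    origin = traj[0] if origin is None else np.asarray(origin, dtype=float)
    disp = traj - origin
    y = lateral_hint - np.dot(lateral_hint, axis) * axis
    y = y / np.linalg.norm(y)
    z = np.cross(axis, y)
    xy = np.column_stack([disp @ y, disp @ z]) * 1e3
    t = np.arange(len(traj), dtype=float) if time is None else np.asarray(time, float)
    return PlanarTrace(t, xy)


def _common_grid(traces: list[PlanarTrace], dt: float = 1e-3) -> np.ndarray:
    t0 = max(tr.time[0] for tr in traces)
    t1 = min(tr.time[-1] for tr in traces)
    return np.arange(t0, t1 + dt / 2, dt)


def circular_mean(angles: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mean resultant direction of a set of angles."""
    w = np.ones_like(angles) if weights is None else weights
    s = np.sum(w * np.sin(angles))
    c = np.sum(w * np.cos(angles))
    return math.atan2(s, c)


def polar_ensemble_average(traces: list[PlanarTrace],
                           dt: float = 1e-3) -> PlanarTrace:
    """Per-timestep polar average: arithmetic mean of displacement
    magnitudes combined with the circular mean of displacement directions.
    Traces are linearly resampled to a common grid first."""
    if not traces:
        raise EvaluationError("empty ensemble")
    grid = _common_grid(traces, dt)
    rs = [tr.resampled(grid) for tr in traces]
    mags = np.stack([tr.magnitude for tr in rs])
    dirs = np.stack([tr.direction for tr in rs])
    mean_mag = mags.mean(axis=0)
    sin_m = np.sin(dirs).mean(axis=0)
    cos_m = np.cos(dirs).mean(axis=0)
    mean_dir = np.arctan2(sin_m, cos_m)
    xy = np.column_stack([mean_mag * np.cos(mean_dir), mean_mag * np.sin(mean_dir)])
    return PlanarTrace(grid, xy)


def sd_ellipse(points: np.ndarray) -> EllipseStats:
    """1-SD covariance ellipse of a 2D point cloud (>= 3 points)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise EvaluationError("sd_ellipse requires at least 3 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    a, b = math.sqrt(evals[1]), math.sqrt(evals[0])
    major = evecs[:, 1]
    return EllipseStats(center=center, semi_axes=(a, b),
                        orientation=math.atan2(major[1], major[0]))


def peak_and_ttp(traces: list[PlanarTrace], method: str,
                 window_ms: float = 800.0, dt: float = 1e-3) -> PeakStats:
    """Peak displacement and time-to-peak within the evaluation window.

    ``peak_of_average``: the peak of the ensemble-average magnitude trace
    (a single TTP, no SD).  ``average_of_peaks``: mean and SD of the
    per-trace peak magnitudes and their individual TTPs.  The peak of the
    average is never larger than the average of the peaks.
    """
    if method not in ("peak_of_average", "average_of_peaks"):
        raise EvaluationError(f"unknown method {method!r}")
    if not traces:
        raise EvaluationError("empty ensemble")
    if method == "peak_of_average":
        avg = polar_ensemble_average(traces, dt)
        mask = avg.time - avg.time[0] <= window_ms / 1e3 + 1e-12
        mag = avg.magnitude[mask]
        i = int(np.argmax(mag))            # earliest global maximum
        return PeakStats(method=method, peak=float(mag[i]),
                         ttp=float(avg.time[mask][i] - avg.time[0]))
    peaks, ttps = [], []
    for tr in traces:
        mask = tr.time - tr.time[0] <= window_ms / 1e3 + 1e-12
        mag = tr.magnitude[mask]
        i = int(np.argmax(mag))
        peaks.append(float(mag[i]))
        ttps.append(float(tr.time[mask][i] - tr.time[0]))
    peaks, ttps = np.array(peaks), np.array(ttps)
    sd = float(np.std(peaks, ddof=1)) if len(peaks) > 1 else 0.0
    tsd = float(np.std(ttps, ddof=1)) if len(ttps) > 1 else 0.0
    return PeakStats(method=method, peak=float(peaks.mean()), ttp=float(ttps.mean()),
                     peak_sd=sd, ttp_sd=tsd)


def within_one_sd(model_peak: float, ensemble: PeakStats) -> bool:
    """True iff the model peak lies within one SD of the ensemble mean
    (closed interval at the boundary)."""
    if ensemble.peak_sd is None:
        raise EvaluationError("ensemble statistics carry no SD")
    return abs(model_peak - ensemble.peak) <= ensemble.peak_sd + 1e-12
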