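"""Shoulder feedback controllers.

Two channels drive the muscles:

* **APF** (angular position feedback): a single PD controller on the
  angular deviation ``theta`` of a humerus-fixed reference vector, measured
  in a local frame with X along the initial humerus long axis and Y
  lateral.  The saturated scalar command is distributed across the
  glenohumeral muscles by the spatial tuning pattern evaluated at the
  deviation direction ``phi`` in the frame's YZ plane, and the pre-loading
  baseline activity is added on top.

* **MLF** (muscle length feedback): an independent PD stretch reflex per
  scapular muscle, responding to lengthening of the whole element chain
  relative to its initial length (in mm), one-sided (no drive on
  shortening).

Both channels see their error through a pure transport delay (30 ms APF,
10 ms MLF) and drive first-order activation dynamics.  Every excitation
and activation is clamped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, ControllerConfig, GainSet, direction_phi
from .stp import SpatialTuningPattern


class DelayLine:
    """Fixed-capacity FIFO implementing a pure transport delay.

    The output at time t equals the input at t - delay once t >= delay;
    before that it returns the initial fill value.  The delay must be an
    integer multiple of the sampling step.
    """

    def __init__(self, delay_ms: float, step_ms: float, initial: float = 0.0):
        if delay_ms < 0 or step_ms <= 0:
            raise ConfigurationError("delay must be >= 0 and step > 0")
        n_exact = delay_ms / step_ms
        n = int(round(n_exact))
        if abs(n_exact - n) > 1e-9:
            raise ConfigurationError(
                f"delay {delay_ms} ms is not an integer multiple of the "
                f"{step_ms} ms step"
            )
        self.delay_ms = delay_ms
        self.step_ms = step_ms
        self._n = n
        self._buf = [float(initial)] * n
        self._ptr = 0

    def step(self, x: float) -> float:
        if self._n == 0:
            return float(x)
        y = self._buf[self._ptr]
        self._buf[self._ptr] = float(x)
        self._ptr = (self._ptr + 1) % self._n
        return y


def delay_step(line: DelayLine, x: float, t_ms: float | None = None) -> float:
    """Advance the delay line one sample and return the delayed value."""
    return line.step(x)


def local_frame(humerus_axis: np.ndarray,
                torso_rotation: np.ndarray | None = None,
                lateral_hint: np.ndarray = np.array([0.0, 1.0, 0.0])) -> np.ndarray:
    """Orthonormal frame (columns X, Y, Z): X along the humerus long axis,
    Y lateral, Z completing the right-handed triad.

    With ``torso_rotation`` given, the axis is first expressed in torso
    coordinates, so that a rigid rotation of torso and humerus together
    leaves deviations at zero (full-body mode); without it the frame is
    fixed to ground (submodel mode).
    """
    ax = np.asarray(humerus_axis, dtype=float)
    n = np.linalg.norm(ax)
    if n < 1e-12:
        raise ConfigurationError("degenerate (zero-length) humerus axis")
    if torso_rotation is not None:
        ax = np.asarray(torso_rotation).T @ ax
        lateral_hint = np.asarray(torso_rotation).T @ lateral_hint
    x = ax / np.linalg.norm(ax)
    y = lateral_hint - np.dot(lateral_hint, x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise ConfigurationError("lateral hint parallel to the humerus axis")
    y = y / ny
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def angular_deviation(ref_current: np.ndarray, ref_initial: np.ndarray,
                      frame: np.ndarray) -> tuple[float, float]:
    """Angle ``theta`` between the current and initial reference vectors and
    the polar direction ``phi`` of the deviation in the frame's YZ plane
    (measured from +Y toward +Z).

    For anti-parallel vectors ``theta`` is pi and ``phi`` is NaN (the
    direction is undefined); for zero deviation ``phi`` is 0.
    """
    a = np.asarray(ref_current, dtype=float)
    b = np.asarray(ref_initial, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("reference vectors must be non-zero")
    a, b = a / na, b / nb
    theta = math.atan2(float(np.linalg.norm(np.cross(b, a))), float(np.dot(a, b)))
    y = float(np.dot(a, frame[:, 1]))
    z = float(np.dot(a, frame[:, 2]))
    if theta < 1e-12:
        return theta, 0.0
    if math.pi - theta < 1e-9:
        return math.pi, float("nan")
    return theta, math.atan2(z, y)


def pd_step(theta_delayed: float, theta_rate: float, gains: GainSet) -> float:
    """Raw PD output ``P*theta + D*theta_rate`` (rate in rad/ms)."""
    return gains.p_apf * theta_delayed + gains.d_apf * theta_rate


def saturate(u: float) -> float:
    """Clamp a command to [0, 1] (min/max saturation)."""
    return min(1.0, max(0.0, float(u)))


def stp_lookup(stp: SpatialTuningPattern, phi: float) -> np.ndarray:
    """Per-muscle weights at deviation direction ``phi``: piecewise-linear
    interpolation in angle between the two adjacent sampled directions,
    periodic over the circle."""
    angles = np.array([direction_phi(d) for d in stp.weights.columns])
    order = np.argsort(angles)
    angles = angles[order]
    table = stp.weights.to_numpy()[:, order]
    phi = float(phi) % (2 * math.pi)
    # periodic extension
    ang_ext = np.concatenate([angles, [angles[0] + 2 * math.pi]])
    tab_ext = np.concatenate([table, table[:, :1]], axis=1)
    idx = int(np.searchsorted(ang_ext, phi, side="right") - 1)
    idx = max(0, min(idx, len(ang_ext) - 2))
    a0, a1 = ang_ext[idx], ang_ext[idx + 1]
    frac = 0.0 if a1 == a0 else (phi - a0) / (a1 - a0)
    return (1 - frac) * tab_ext[:, idx] + frac * tab_ext[:, idx + 1]


def apf_excitations(u_sat: float, weights: np.ndarray,
                    baseline: np.ndarray) -> np.ndarray:
    """Per-muscle excitation: baseline plus STP-weighted command, clamped."""
    return np.clip(np.asarray(baseline, float) + np.asarray(weights, float) * u_sat,
                   0.0, 1.0)


def activation_step(a: float, u: float, dt_ms: float,
                    tau_act_ms: float, tau_deact_ms: float) -> float:
    """One step of first-order activation dynamics ``da/dt = (u - a)/tau``
    (exact exponential update), with the faster time constant when the
    excitation exceeds the activation."""
    if tau_act_ms <= 0 or tau_deact_ms <= 0:
        raise ConfigurationError("activation time constants must be > 0")
    tau = tau_act_ms if u >= a else tau_deact_ms
    a_new = u + (a - u) * math.exp(-dt_ms / tau)
    return min(1.0, max(0.0, a_new))


def mlf_step(elongation_mm: float, elongation_rate: float, gains: GainSet,
             baseline: float = 0.0) -> float:
    """Stretch-reflex excitation: responds to lengthening only (rate in
    mm/ms); baseline plus the one-sided PD term, clamped to [0, 1]."""
    drive = max(0.0, gains.p_mlf * elongation_mm + gains.d_mlf * elongation_rate)
    return min(1.0, max(0.0, baseline + drive))


def calibrate_gains(theta_trace: np.ndarray, dt_ms: float, delay_ms: float,
                    base: GainSet | None = None, label: str = "calibrated") -> GainSet:
    """Set P and D so that each term's maximum contribution over a passive
    error trace is exactly 1: ``P = 1/max|theta_delayed|``,
    ``D = 1/max|d theta_delayed / dt|``."""
    theta = np.asarray(theta_trace, dtype=float)
    delayed = delayed_trace(theta, dt_ms, delay_ms)
    rate = np.diff(delayed, prepend=delayed[0]) / dt_ms
    max_t, max_r = float(np.max(np.abs(delayed))), float(np.max(np.abs(rate)))
    if max_t <= 0 or max_r <= 0:
        raise ValueError("calibration requires a non-constant error trace")
    base = base or GainSet()
    return GainSet(p_apf=1.0 / max_t, d_apf=1.0 / max_r,
                   p_mlf=base.p_mlf, d_mlf=base.d_mlf, label=label)


def delayed_trace(x: np.ndarray, dt_ms: float, delay_ms: float,
                  initial: float = 0.0) -> np.ndarray:
    """Apply a pure transport delay to a sampled trace (array shift)."""
    line = DelayLine(delay_ms, dt_ms, initial=initial)
    return np.array([line.step(v) for v in np.asarray(x, dtype=float)])


# --------------------------------------------------------------- controllers

@dataclass
class ApfChannelLog:
    theta: list = field(default_factory=list)
    phi: list = field(default_factory=list)
    u_raw: list = field(default_factory=list)
    u_sat: list = field(default_factory=list)


class ApfChannel:
    """The scalar APF pipeline: delayed theta -> PD -> saturation, plus the
    delayed deviation direction used for spatial tuning."""

    def __init__(self, gains: GainSet, delay_ms: float, dt_ms: float):
        self.gains = gains
        self.theta_line = DelayLine(delay_ms, dt_ms)
        self.phi_line = DelayLine(delay_ms, dt_ms)
        self.dt_ms = dt_ms
        self._prev_delayed = 0.0
        self.log = ApfChannelLog()

    def step(self, theta: float, phi: float) -> tuple[float, float]:
        """Returns (u_sat, phi_delayed)."""
        th_d = self.theta_line.step(theta)
        ph_d = self.phi_line.step(phi if math.isfinite(phi) else 0.0)
        rate = (th_d - self._prev_delayed) / self.dt_ms
        self._prev_delayed = th_d
        u_raw = pd_step(th_d, rate, self.gains)
        u_sat = saturate(u_raw)
        self.log.theta.append(theta)
        self.log.phi.append(phi)
        self.log.u_raw.append(u_raw)
        self.log.u_sat.append(u_sat)
        return u_sat, ph_d


class ShoulderController:
    """Combined APF + MLF controller bound to a model's muscle list.

    ``stp`` must already be rescaled for the controller (each direction
    column maximum = 1) and cover every APF muscle.  MLF muscles use the
    scalar ``mlf_baseline`` from the configuration.
    """

    def __init__(self, cfg: ControllerConfig, stp: SpatialTuningPattern,
                 muscle_names: list[str], assignments: dict[str, str],
                 dt_ms: float, shoulder_fractions: dict[str, float] | None = None):
        self.cfg = cfg
        self.dt_ms = dt_ms
        self.muscle_names = list(muscle_names)
        self.apf_idx = [i for i, n in enumerate(muscle_names)
                        if assignments.get(n) == "apf"]
        self.mlf_idx = [i for i, n in enumerate(muscle_names)
                        if assignments.get(n) == "mlf"]
        apf_names = [muscle_names[i] for i in self.apf_idx]
        missing = [n for n in apf_names if n not in stp.weights.index]
        if missing:
            raise ConfigurationError(f"STP missing APF muscles: {missing}")
        self.stp = stp.restricted(apf_names)
        self.apf = ApfChannel(cfg.gains, cfg.apf_delay_ms, dt_ms)
        self.apf_baseline = self.stp.baseline.to_numpy()
        fr = shoulder_fractions or {}
        self.apf_fraction = np.array([fr.get(n, 1.0) for n in apf_names])
        self.mlf_lines = [DelayLine(cfg.mlf_delay_ms, dt_ms) for _ in self.mlf_idx]
        self._mlf_prev = np.zeros(len(self.mlf_idx))
        self.excitations = np.zeros(len(muscle_names))
        self.activations = np.zeros(len(muscle_names))
        # start from tonic baseline activity
        for j, i in enumerate(self.apf_idx):
            self.excitations[i] = self.apf_baseline[j]
        for i in self.mlf_idx:
            self.excitations[i] = cfg.mlf_baseline
        self.activations[:] = self.excitations

    def baseline_activations(self) -> np.ndarray:
        out = np.zeros(len(self.muscle_names))
        for j, i in enumerate(self.apf_idx):
            out[i] = self.apf_baseline[j] * self.apf_fraction[j]
        for i in self.mlf_idx:
            out[i] = self.cfg.mlf_baseline
        return out

    def step(self, theta: float, phi: float,
             elongations_mm: np.ndarray) -> np.ndarray:
        """Advance one control step; returns per-muscle activations scaled
        by the shoulder PCSA fraction for bi-articular APF muscles."""
        u_sat, phi_d = self.apf.step(theta, phi)
        weights = stp_lookup(self.stp, phi_d)
        u_apf = apf_excitations(u_sat, weights, self.apf_baseline)
        for j, i in enumerate(self.apf_idx):
            self.excitations[i] = u_apf[j]
        g = self.cfg.gains
        for j, i in enumerate(self.mlf_idx):
            e_d = self.mlf_lines[j].step(float(elongations_mm[i]))
            rate = (e_d - self._mlf_prev[j]) / self.dt_ms
            self._mlf_prev[j] = e_d
            self.excitations[i] = mlf_step(e_d, rate, g, self.cfg.mlf_baseline)
        for i in range(len(self.muscle_names)):
            self.activations[i] = activation_step(
                self.activations[i], self.excitations[i], self.dt_ms,
                self.cfg.tau_act_ms, self.cfg.tau_deact_ms,
            )
        out = self.activations.copy()
        for j, i in enumerate(self.apf_idx):
            out[i] *= self.apf_fraction[j]
        return out
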