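"""Deterministic synthetic-data generators.

Two generators emulate the structure of the volunteer experiment the
controller draws on (no public deposition of those data exists):

* ``generate_emg`` produces MVIC-scaled surface-EMG envelopes for 13
  muscles x 8 loading directions x 17 subjects, with pre-loading baseline
  activity and a direction-tuned burst peaking within the first second of
  loading, plus the generating tuning table as ground truth.  The tuning is
  a rectified cosine around each muscle's preferred loading direction
  (the direction opposite its mechanical action, i.e. the load it resists),
  raised to a sharpness power.

* ``generate_volunteer_ensemble`` produces 2D elbow-displacement traces
  shaped as under-damped second-order returns: per-subject peak and
  time-to-peak drawn from per-direction normal distributions, direction
  jittered around the loading direction, decaying back toward the origin
  within the 800 ms evaluation window.

All draws come from a single seeded generator; identical parameters and
seed give bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import DIRECTIONS, direction_phi
from .evaluation import PlanarTrace
from .stp import EmgRecording, MvicTable

# The 13 muscles instrumented in the emulated experiment, with the loading
# direction (deg, evaluation-plane polar angle) each one prefers; for the
# glenohumeral muscles this is approximately opposite the action direction
# of the reference arm model (the load each muscle is best placed to
# resist).
DEFAULT_TUNING_DEG: dict[str, float] = {
    "ant_deltoid": 307.0,
    "mid_deltoid": 206.0,
    "post_deltoid": 110.0,
    "pect_major_clav": 342.0,
    "pect_major_stern": 19.0,
    "latissimus_dorsi": 52.0,
    "infraspinatus": 317.0,
    "biceps_brachii": 277.0,
    "triceps_brachii": 77.0,
    "upper_trapezius": 45.0,
    "middle_trapezius": 315.0,
    "lower_trapezius": 270.0,
    "serratus_anterior": 135.0,
}


@dataclass
class EmgFixtureParams:
    n_subjects: int = 17
    muscles: tuple[str, ...] = tuple(DEFAULT_TUNING_DEG)
    directions: tuple[str, ...] = DIRECTIONS
    preferred_deg: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TUNING_DEG))
    amplitude: float = 0.6          # tuned burst amplitude, MVIC fraction
    sharpness: float = 2.0          # cosine exponent
    floor: float = 0.05             # untuned co-contraction floor of the burst
    baseline_level: float = 0.04    # pre-loading activity, MVIC fraction
    noise_sd: float = 0.05          # additive noise SD, MVIC fraction
    mvic_scale: tuple[float, float] = (0.5, 2.0)
    sample_rate: float = 500.0      # Hz
    pre_s: float = 0.6              # recording before loading onset
    post_s: float = 1.5             # recording after onset
    burst_peak_s: float = 0.3       # burst peak time after onset
    burst_width_s: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude + self.baseline_level > 1.0:
            raise ValueError("amplitude + baseline must not exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def tuning_weight(phi: float, preferred: float, sharpness: float,
                  floor: float = 0.0) -> float:
    """Rectified-cosine directional tuning raised to the sharpness power,
    on top of an untuned floor."""
    c = max(0.0, math.cos(phi - preferred))
    return floor + (1.0 - floor) * c ** sharpness


def generate_emg(params: EmgFixtureParams
                 ) -> tuple[list[EmgRecording], MvicTable, "np.ndarray | object"]:
    """Generate recordings, the MVIC table, and the ground-truth STP.

    The ground truth is the table a noise-free STP build should recover:
    normalized windowed peaks (baseline + tuned burst amplitude) with the
    bi-articular shoulder/elbow ratios already divided out, plus the
    baseline column, as a pandas DataFrame with a ``baseline`` column.
    """
    import pandas as pd
    from .stp import BiarticularRatios, _biarticular_divisor

    rng = np.random.default_rng(params.seed)
    ratios = BiarticularRatios()
    sr = params.sample_rate
    n_pre = int(round(params.pre_s * sr))
    n_post = int(round(params.post_s * sr))
    t_post = np.arange(n_post) / sr
    burst = np.exp(-(((t_post - params.burst_peak_s) / params.burst_width_s) ** 2))

    recordings: list[EmgRecording] = []
    mvic_values: dict[tuple[str, str], float] = {}
    clip_hi = 1.0 + 5.0 * params.noise_sd
    for s in range(params.n_subjects):
        subject = f"S{s + 1:02d}"
        for muscle in params.muscles:
            lo, hi = params.mvic_scale
            mvic = float(rng.uniform(lo, hi))
            mvic_values[(subject, muscle)] = mvic
            pref = math.radians(params.preferred_deg[muscle])
            for d in params.directions:
                w = params.amplitude * tuning_weight(
                    direction_phi(d), pref, params.sharpness, params.floor)
                sig = np.concatenate([
                    np.full(n_pre, params.baseline_level),
                    params.baseline_level + w * burst,
                ])
                if params.noise_sd > 0:
                    sig = sig + rng.normal(0.0, params.noise_sd, len(sig))
                sig = np.clip(sig, 0.0, clip_hi)
                recordings.append(EmgRecording(
                    subject=subject, muscle=muscle, direction=d,
                    samples=sig * mvic, sample_rate=sr,
                    loading_onset=params.pre_s,
                ))
    truth = pd.DataFrame(index=list(params.muscles), columns=list(DIRECTIONS),
                         dtype=float)
    base = {}
    for muscle in params.muscles:
        div = _biarticular_divisor(muscle, ratios)
        pref = math.radians(params.preferred_deg[muscle])
        for d in DIRECTIONS:
            w = params.amplitude * tuning_weight(
                direction_phi(d), pref, params.sharpness, params.floor)
            truth.loc[muscle, d] = (params.baseline_level + w) / div
        base[muscle] = params.baseline_level / div
    truth["baseline"] = pd.Series(base)
    return recordings, MvicTable(mvic_values), truth


# default per-direction volunteer peak envelope (mm) and spread; chosen to
# echo the qualitative pattern of seated volunteers under an 8 kg elbow
# drop: peaks of order 100-300 mm, smaller in the adduction directions
# where the arm meets the torso, time-to-peak a few hundred ms.
DEFAULT_PEAK_MM: dict[str, tuple[float, float]] = {
    "flexion": (180.0, 50.0),
    "flexion_adduction": (160.0, 45.0),
    "adduction": (130.0, 40.0),
    "extension_adduction": (140.0, 40.0),
    "extension": (170.0, 50.0),
    "extension_abduction": (170.0, 50.0),
    "abduction": (180.0, 50.0),
    "flexion_abduction": (190.0, 55.0),
}


@dataclass
class KinFixtureParams:
    n_subjects: int = 17
    peak_mm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_MM))
    ttp_s: tuple[float, float] = (0.25, 0.06)
    damping_ratio: float = 0.35
    scatter_sd: float = 0.15        # rad, directional jitter
    duration: float = 1.0           # s
    dt: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.damping_ratio < 2.0:
            raise ValueError("damping_ratio must be in (0, 2)")
        for d, (mu, sd) in self.peak_mm.items():
            if sd < 0:
                raise ValueError(f"{d}: SD must be >= 0")
        if self.ttp_s[1] < 0 or self.scatter_sd < 0:
            raise ValueError("SDs must be >= 0")


def _damped_profile(t: np.ndarray, peak: float, ttp: float,
                    zeta: float) -> np.ndarray:
    """Under-damped second-order displacement along the loading direction,
    scaled so the first maximum equals ``peak`` at ``t = ttp``."""
    wd = math.atan2(math.sqrt(max(1e-12, 1.0 - zeta ** 2)), zeta) / ttp
    wn = wd / math.sqrt(max(1e-12, 1.0 - zeta ** 2))
    raw = np.exp(-zeta * wn * t) * np.sin(wd * t)
    ref = math.exp(-zeta * wn * ttp) * math.sin(wd * ttp)
    return peak * raw / ref


def generate_volunteer_ensemble(params: KinFixtureParams,
                                direction: str) -> list[PlanarTrace]:
    """Synthetic volunteer elbow-displacement ensemble for one direction."""
    rng = np.random.default_rng(params.seed + 1)
    mu, sd = params.peak_mm[direction]
    phi0 = direction_phi(direction)
    t = np.arange(0.0, params.duration + params.dt / 2, params.dt)
    traces = []
    for _ in range(params.n_subjects):
        peak = -1.0
        for _ in range(100):
            peak = float(rng.normal(mu, sd))
            if peak > 0:
                break
        else:
            raise RuntimeError("could not draw a positive peak")
        ttp = -1.0
        for _ in range(100):
            ttp = float(rng.normal(*params.ttp_s))
            if ttp > 0.05:
                break
        phi = phi0 + float(rng.normal(0.0, params.scatter_sd))
        r = _damped_profile(t, peak, ttp, params.damping_ratio)
        xy = np.column_stack([r * math.cos(phi), r * math.sin(phi)])
        traces.append(PlanarTrace(t.copy(), xy))
    return traces
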