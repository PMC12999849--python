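"""Configuration types and loading.

All quantities in the configuration file use m, kg, s, N and degrees;
angles are converted to radians internally.  A bundled default model file
(``data/default_model.yaml``) defines the reference arm, controller and
weight-drop protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a model/experiment configuration is invalid."""


# Canonical loading-direction labels (order as reported in the protocol)
# and their polar angle phi in the evaluation plane, measured
# counterclockwise from +Y (lateral) toward +Z (superior).
DIRECTION_PHI_DEG: dict[str, float] = {
    "flexion": 90.0,
    "extension": 270.0,
    "adduction": 180.0,
    "abduction": 0.0,
    "flexion_adduction": 135.0,
    "flexion_abduction": 45.0,
    "extension_adduction": 225.0,
    "extension_abduction": 315.0,
}
DIRECTIONS: tuple[str, ...] = tuple(DIRECTION_PHI_DEG)


def direction_phi(label: str) -> float:
    """Polar angle (rad) of a loading-direction label in the YZ plane."""
    try:
        return math.radians(DIRECTION_PHI_DEG[label])
    except KeyError:
        raise ConfigurationError(
            f"unknown direction {label!r}; valid directions: "
            + ", ".join(DIRECTIONS)
        ) from None


@dataclass
class SegmentSpec:
    name: str
    mass: float
    inertia: np.ndarray          # 3x3 about the COM, kg m^2
    com_offset: np.ndarray       # COM in the segment frame, m
    parent: Optional[str] = None  # None / "ground" for the root

    def __post_init__(self) -> None:
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(3, 3)
        self.com_offset = np.asarray(self.com_offset, dtype=float).reshape(3)
        if self.mass <= 0:
            raise ConfigurationError(f"segment {self.name}: mass must be > 0")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise ConfigurationError(f"segment {self.name}: inertia not symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) <= 0):
            raise ConfigurationError(
                f"segment {self.name}: inertia not positive definite"
            )


JOINT_KINDS = ("spherical_3dof", "locked", "planar_2dof")
JOINT_DOF = {"spherical_3dof": 3, "locked": 0, "planar_2dof": 2}


@dataclass
class JointSpec:
    name: str
    kind: str
    parent: str
    child: str
    parent_anchor: np.ndarray          # joint location in the parent frame, m
    child_anchor: np.ndarray | None = None
    # planar: two translation axes (columns, parent frame); locked: fixed
    # rotation as a rotation vector (rad) taking parent axes to child axes.
    axes: np.ndarray | None = None
    locked_rotvec: np.ndarray | None = None
    rotation_limits: Sequence[tuple[float, float]] | None = None  # rad or m
    stop_stiffness: float = 0.0        # N m/rad (or N/m for planar)
    stop_damping: float = 0.0
    viscous_damping: float = 0.0       # always-on joint damping per DOF
    centering_stiffness: float = 0.0   # elastic return toward q=0 (planar)
    centering_damping: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in JOINT_KINDS:
            raise ConfigurationError(f"joint {self.name}: unknown kind {self.kind!r}")
        self.parent_anchor = np.asarray(self.parent_anchor, dtype=float).reshape(3)
        if self.child_anchor is None:
            self.child_anchor = np.zeros(3)
        self.child_anchor = np.asarray(self.child_anchor, dtype=float).reshape(3)
        if self.kind == "planar_2dof":
            if self.axes is None:
                self.axes = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
            self.axes = np.asarray(self.axes, dtype=float).reshape(3, 2)
        if self.locked_rotvec is not None:
            self.locked_rotvec = np.asarray(self.locked_rotvec, dtype=float).reshape(3)
        if self.rotation_limits is not None:
            lims = [tuple(map(float, lim)) for lim in self.rotation_limits]
            for lo, hi in lims:
                if not lo < hi:
                    raise ConfigurationError(
                        f"joint {self.name}: limit ({lo}, {hi}) is not a proper interval"
                    )
            if len(lims) != JOINT_DOF[self.kind]:
                raise ConfigurationError(
                    f"joint {self.name}: expected {JOINT_DOF[self.kind]} limit pairs"
                )
            self.rotation_limits = lims

    @property
    def dof(self) -> int:
        return JOINT_DOF[self.kind]


@dataclass
class HillParams:
    """Hill-type curve shapes; any standard parameterization is acceptable
    and these are exposed in the configuration file."""

    fl_width: float = 0.45        # Gaussian force-length width (dimensionless)
    a_rel: float = 0.25           # Hill hyperbola a/F0
    v_max: float = 10.0           # max shortening velocity, optimal lengths/s
    fv_ecc_plateau: float = 1.5   # eccentric force-velocity asymptote
    passive_scale: float = 0.05   # passive curve scale (fraction of F_max)
    passive_rate: float = 8.0     # passive exponential rate
    damping: float = 0.1          # parallel damping, F_max per unit v/v_max


@dataclass
class MuscleSpec:
    name: str
    pcsa: float                  # cm^2
    path: list[tuple[str, np.ndarray]]   # (segment, local point); >= 2 entries
    specific_tension: float = 50.0       # N/cm^2
    optimal_length: float | None = None  # None -> initial path length
    controller_assignment: str = "none"  # apf | mlf | elbow | none
    shoulder_fraction: float = 1.0
    action_phi_deg: float | None = None  # anatomical action direction, for
                                         # the isolated-activation routing check

    def __post_init__(self) -> None:
        if self.pcsa <= 0:
            raise ConfigurationError(f"muscle {self.name}: pcsa must be > 0")
        if not 0.0 <= self.shoulder_fraction <= 1.0:
            raise ConfigurationError(
                f"muscle {self.name}: shoulder_fraction must be in [0, 1]"
            )
        if len(self.path) < 2:
            raise ConfigurationError(f"muscle {self.name}: need >= 2 path points")
        if self.optimal_length is not None and self.optimal_length <= 0:
            raise ConfigurationError(
                f"muscle {self.name}: optimal_length must be positive"
            )
        self.path = [(seg, np.asarray(p, dtype=float).reshape(3)) for seg, p in self.path]


@dataclass
class ModelConfig:
    segments: list[SegmentSpec]
    joints: list[JointSpec]
    muscles: list[MuscleSpec] = field(default_factory=list)
    elbow_angle_deg: float = 130.0
    gravity: float = 9.81
    hill: HillParams = field(default_factory=HillParams)
    gravity_compensation: bool = True
    integrator: str = "semi_implicit"   # or "rk4"
    dt: float = 1e-3                    # s

    def __post_init__(self) -> None:
        if not 0.0 < self.elbow_angle_deg < 180.0:
            raise ConfigurationError("elbow_angle_deg must be in (0, 180)")
        names = {s.name for s in self.segments}
        if len(names) != len(self.segments):
            raise ConfigurationError("duplicate segment names")
        for j in self.joints:
            if j.child not in names:
                raise ConfigurationError(f"joint {j.name}: unknown child {j.child}")
            if j.parent not in names and j.parent != "ground":
                raise ConfigurationError(f"joint {j.name}: unknown parent {j.parent}")
        for m in self.muscles:
            for seg, _ in m.path:
                if seg not in names:
                    raise ConfigurationError(
                        f"muscle {m.name} references unknown segment {seg!r}"
                    )


@dataclass
class GainSet:
    """PD gains.  APF gains act on the humerus angle error (1/rad and
    1/(rad ms^-1)); MLF gains act on muscle elongation (1/mm, 1/(mm ms^-1))."""

    p_apf: float = 1.6
    d_apf: float = 150.0
    p_mlf: float = 0.5
    d_mlf: float = 5.0
    label: str = "Baseline"

    def __post_init__(self) -> None:
        for g in (self.p_apf, self.d_apf, self.p_mlf, self.d_mlf):
            if g < 0:
                raise ConfigurationError("gains must be >= 0")

    def scaled(self, p_factor: float = 1.0, d_factor: float = 1.0,
               label: str | None = None) -> "GainSet":
        return GainSet(self.p_apf * p_factor, self.d_apf * d_factor,
                       self.p_mlf, self.d_mlf, label or self.label)


@dataclass
class ControllerConfig:
    gains: GainSet = field(default_factory=GainSet)
    apf_delay_ms: float = 30.0
    mlf_delay_ms: float = 10.0
    tau_act_ms: float = 15.0
    tau_deact_ms: float = 40.0
    mlf_baseline: float = 0.01
    frame_mode: str = "ground"   # ground (submodel) | torso (full body)
    stp_path: str | None = None  # None -> bundled default table

    def __post_init__(self) -> None:
        if self.apf_delay_ms < 0 or self.mlf_delay_ms < 0:
            raise ConfigurationError("delays must be >= 0")
        if self.tau_act_ms <= 0 or self.tau_deact_ms <= 0:
            raise ConfigurationError("activation time constants must be > 0")
        if self.frame_mode not in ("ground", "torso"):
            raise ConfigurationError("frame_mode must be 'ground' or 'torso'")


@dataclass
class ExperimentConfig:
    drop_mass: float = 8.0              # kg
    initial_mass_velocity: float = 0.77  # m/s, downward
    routing_distance: float = 1.5       # m from the elbow along each direction
    attachment: tuple[str, np.ndarray] = ("forearm", np.zeros(3))
    duration: float = 1.0               # s
    directions: tuple[str, ...] = DIRECTIONS
    routing_points: dict[str, list[np.ndarray]] | None = None  # override

    def __post_init__(self) -> None:
        if self.drop_mass <= 0:
            raise ConfigurationError("drop_mass must be > 0")
        seg, p = self.attachment
        self.attachment = (seg, np.asarray(p, dtype=float).reshape(3))
        for d in self.directions:
            direction_phi(d)


@dataclass
class EvaluationConfig:
    window_ms: float = 800.0


@dataclass
class Config:
    model: ModelConfig
    controller: ControllerConfig
    experiment: ExperimentConfig
    evaluation: EvaluationConfig


def _seg_from_dict(d: dict) -> SegmentSpec:
    inertia = d["inertia"]
    if np.asarray(inertia).size == 3:        # principal moments shorthand
        inertia = np.diag(np.asarray(inertia, dtype=float))
    return SegmentSpec(
        name=d["name"], mass=float(d["mass"]), inertia=inertia,
        com_offset=d.get("com_offset", np.zeros(3)), parent=d.get("parent"),
    )


def _joint_from_dict(d: dict) -> JointSpec:
    d = dict(d)
    for key in ("parent_anchor", "child_anchor", "axes", "locked_rotvec"):
        if key in d:
            d[key] = np.asarray(d[key], dtype=float)
    if "locked_angle_deg" in d:
        axis = np.asarray(d.pop("locked_axis", [0.0, 0.0, 1.0]), dtype=float)
        ang = math.radians(float(d.pop("locked_angle_deg")))
        d["locked_rotvec"] = axis / np.linalg.norm(axis) * ang
    return JointSpec(**d)


def _muscle_from_dict(d: dict) -> MuscleSpec:
    d = dict(d)
    d["path"] = [(p["segment"], np.asarray(p["point"], dtype=float)) for p in d["path"]]
    return MuscleSpec(**d)


def default_config_path() -> Path:
    return Path(str(resources.files("shoulderctl") / "data" / "default_model.yaml"))


def load_config(path: str | Path | None = None) -> Config:
    """Load a full configuration; ``path=None`` loads the bundled default."""
    if path is None:
        path = default_config_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        mraw = raw.get("model", {})
        model = ModelConfig(
            segments=[_seg_from_dict(s) for s in mraw["segments"]],
            joints=[_joint_from_dict(j) for j in mraw["joints"]],
            muscles=[_muscle_from_dict(m) for m in mraw.get("muscles", [])],
            elbow_angle_deg=float(mraw.get("elbow_angle_deg", 130.0)),
            gravity=float(mraw.get("gravity", 9.81)),
            hill=HillParams(**mraw.get("hill", {})),
            gravity_compensation=bool(mraw.get("gravity_compensation", True)),
            integrator=mraw.get("integrator", "semi_implicit"),
            dt=float(mraw.get("dt", 1e-3)),
        )
        craw = dict(raw.get("controller", {}))
        gains = GainSet(**craw.pop("gains", {}))
        controller = ControllerConfig(gains=gains, **craw)
        eraw = dict(raw.get("experiment", {}))
        if "attachment" in eraw:
            att = eraw["attachment"]
            eraw["attachment"] = (att["segment"], np.asarray(att["point"], dtype=float))
        if "directions" in eraw:
            eraw["directions"] = tuple(eraw["directions"])
        experiment = ExperimentConfig(**eraw)
        evaluation = EvaluationConfig(**raw.get("evaluation", {}))
    except KeyError as exc:
        raise ConfigurationError(f"missing configuration key: {exc}") from exc
    return Config(model=model, controller=controller,
                  experiment=experiment, evaluation=evaluation)
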