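"""Weight-drop verification protocol.

An 8 kg point mass is dropped on a cable routed over frictionless pulleys
to the elbow, loading it in one of eight directions in the plane
perpendicular to the initial humerus axis.  The cable is massless and
inextensible: while taut, the mass and the arm share a single tension, and
the mass's vertical motion is kinematically tied to the elbow-to-pulley
path length.  The mass starts with a downward velocity (slack in the
release mechanism), engaging the cable through an inelastic impulse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import (
    Config,
    ConfigurationError,
    DIRECTIONS,
    ExperimentConfig,
    GainSet,
    ModelConfig,
    ControllerConfig,
    direction_phi,
)
from .control import ShoulderController, angular_deviation, local_frame
from .model import ArmModel, SimulationDivergedError, build_arm_model
from .stp import SpatialTuningPattern, rescale_for_controller


@dataclass
class TrialResult:
    """Time histories of one weight-drop trial."""

    direction: str
    gain_label: str
    time: np.ndarray                 # (n,), s
    elbow: np.ndarray                # (n, 3), m
    tension: np.ndarray              # (n,), N
    theta: np.ndarray                # (n,), rad
    phi: np.ndarray                  # (n,), rad
    excitations: np.ndarray          # (n, n_muscles)
    activations: np.ndarray          # (n, n_muscles)
    muscle_names: list[str]
    reference_axis: np.ndarray       # initial humerus axis
    elbow0: np.ndarray               # initial elbow position
    meta: dict = field(default_factory=dict)

    def peak_theta(self) -> float:
        return float(np.max(np.abs(self.theta)))

    def saturation_fraction(self) -> float:
        u = self.meta.get("u_sat")
        if u is None:
            return 0.0
        u = np.asarray(u)
        return float(np.mean(u >= 1.0 - 1e-12)) if len(u) else 0.0


def cable_tension_and_force(mass_state, routing_points, attachment_point):
    """Tension and elbow force of a massless inextensible cable.

    ``mass_state`` is ``(mass_kg, accel_down, slack)``: the suspended
    mass, its downward acceleration, and whether the cable is slack.  The
    tension is uniform along the cable (frictionless routing) and the
    force on the elbow points from the attachment toward the first routing
    point.  A slack cable carries no tension.
    """
    mass_kg, accel_down, slack = mass_state
    routing = [np.asarray(p, dtype=float) for p in np.atleast_2d(routing_points)]
    attach = np.asarray(attachment_point, dtype=float)
    d = routing[0] - attach
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise ConfigurationError("attachment coincides with a routing point")
    if slack:
        return 0.0, np.zeros(3)
    tension = mass_kg * (9.81 - accel_down)
    return float(tension), tension * d / n


class Cable:
    """Inextensible cable coupling the drop mass to the elbow attachment.

    Tracks the mass's fall depth ``y`` (m, downward positive) below the
    engagement reference and switches between taut (bilateral constraint
    with non-negative tension) and slack (free-falling mass) states.
    """

    def __init__(self, model: ArmModel, direction: str, cfg: ExperimentConfig):
        self.mass = cfg.drop_mass
        self.attach_seg, self.attach_loc = cfg.attachment
        elbow0 = model.point_world(model.fk(model.q), self.attach_seg,
                                   self.attach_loc)
        if cfg.routing_points and direction in cfg.routing_points:
            self.routing = [np.asarray(p, float) for p in cfg.routing_points[direction]]
        else:
            phi = direction_phi(direction)
            axis = model.reference_axis
            y = np.array([0.0, 1.0, 0.0]) - axis[1] * axis
            y /= np.linalg.norm(y)
            z = np.cross(axis, y)
            u = math.cos(phi) * y + math.sin(phi) * z
            self.routing = [elbow0 + cfg.routing_distance * u]
        self.l0 = float(np.linalg.norm(self.routing[0] - elbow0))
        self.y = 0.0                       # depth below engagement reference
        self.v = cfg.initial_mass_velocity  # downward positive
        self.slack = True
        self.g = 9.81

    def length(self, attach_world: np.ndarray) -> float:
        return float(np.linalg.norm(self.routing[0] - attach_world))

    def free_length(self, attach_world: np.ndarray) -> float:
        """Cable available to the mass side: grows as the elbow approaches
        the pulley."""
        return self.l0 - self.length(attach_world)

    def gap(self, attach_world: np.ndarray) -> float:
        return self.free_length(attach_world) - self.y


def run_trial(model_cfg: ModelConfig,
              controller_cfg: ControllerConfig | None,
              stp: SpatialTuningPattern | None,
              direction: str,
              exp_cfg: ExperimentConfig,
              dt: float | None = None,
              gain_label: str | None = None) -> TrialResult:
    """Simulate one weight-drop trial (passive if ``controller_cfg`` is
    None).  Deterministic for a fixed configuration."""
    if direction not in exp_cfg.directions:
        raise ConfigurationError(
            f"direction {direction!r} not configured; valid: "
            + ", ".join(DIRECTIONS))
    dt = dt if dt is not None else model_cfg.dt
    dt_ms = dt * 1e3
    model = build_arm_model(model_cfg)
    names = model.muscle_names()
    assignments = {m.name: m.controller_assignment for m in model_cfg.muscles}
    fractions = {m.name: m.shoulder_fraction for m in model_cfg.muscles}

    controller = None
    if controller_cfg is not None:
        if stp is None:
            raise ConfigurationError("active trials need a spatial tuning pattern")
        apf_names = [n for n in names if assignments.get(n) == "apf"]
        stp_ctrl = rescale_for_controller(stp, apf_names)
        controller = ShoulderController(controller_cfg, stp_ctrl, names,
                                        assignments, dt_ms,
                                        shoulder_fractions=fractions)
        model.set_feedforward(controller.baseline_activations())
        activations = controller.baseline_activations()
    else:
        model.set_feedforward()
        activations = np.zeros(len(names))

    cable = Cable(model, direction, exp_cfg)
    frame = local_frame(model.reference_axis)
    rest = model.muscle_rest_lengths()

    n_steps = int(round(exp_cfg.duration / dt))
    nt = n_steps + 1
    t_arr = np.zeros(nt)
    elbow_arr = np.zeros((nt, 3))
    tension_arr = np.zeros(nt)
    theta_arr = np.zeros(nt)
    phi_arr = np.zeros(nt)
    exc_arr = np.zeros((nt, len(names)))
    act_arr = np.zeros((nt, len(names)))
    u_sat_log = np.zeros(nt)

    for i in range(nt):
        kin = model.fk(model.q)
        axis = model.humerus_axis(kin)
        theta, phi = angular_deviation(axis, model.reference_axis, frame)
        elbow = model.elbow_point(kin)
        attach = model.point_world(kin, cable.attach_seg, cable.attach_loc)

        if controller is not None:
            elong = (model._path_lengths(kin) - rest) * 1e3  # mm
            activations = controller.step(theta, phi if math.isfinite(phi) else 0.0,
                                          elong)
            exc_arr[i] = controller.excitations
            act_arr[i] = controller.activations
            u_sat_log[i] = controller.apf.log.u_sat[-1]

        t_arr[i] = model.time
        elbow_arr[i] = elbow
        theta_arr[i] = theta
        phi_arr[i] = phi if math.isfinite(phi) else 0.0

        if i == n_steps:
            tension_arr[i] = tension_arr[i - 1] if i else 0.0
            break

        tension_arr[i] = _step_coupled(model, cable, activations, dt)

    meta = {"u_sat": u_sat_log if controller is not None else None,
            "dt": dt, "duration": exp_cfg.duration,
            "drop_mass": cable.mass}
    label = gain_label or (controller_cfg.gains.label if controller_cfg else "Passive")
    return TrialResult(direction=direction, gain_label=label, time=t_arr,
                       elbow=elbow_arr, tension=tension_arr, theta=theta_arr,
                       phi=phi_arr, excitations=exc_arr, activations=act_arr,
                       muscle_names=names, reference_axis=model.reference_axis,
                       elbow0=model.elbow0, meta=meta)


def _step_coupled(model: ArmModel, cable: Cable, activations: np.ndarray,
                  dt: float) -> float:
    """Advance arm + mass one step; returns the cable tension applied."""
    q, qd = model.q, model.qd
    m_mat, q_force, kin, basis_vels, _, _, tensions = model._assemble(
        q, qd, activations, None)
    model.last_tensions = tensions

    attach = model.point_world(kin, cable.attach_seg, cable.attach_loc)
    b = model.body_id(cable.attach_seg)
    # dl/dq of the elbow-to-pulley distance
    u = attach - cable.routing[0]
    ln = np.linalg.norm(u)
    u = u / ln
    grad_l = np.array([
        float(np.dot(u, model.point_velocity(kin, bv, b, attach)))
        for bv in basis_vels
    ])
    tension = 0.0

    if cable.slack:
        # free-falling mass (exact constant-acceleration update)
        qdd = np.linalg.solve(m_mat, q_force)
        model.qd = qd + dt * qdd
        model.q = q + dt * model.qd
        cable.y += cable.v * dt + 0.5 * cable.g * dt * dt
        cable.v += cable.g * dt
        kin2 = model.fk(model.q)
        attach2 = model.point_world(kin2, cable.attach_seg, cable.attach_loc)
        if cable.gap(attach2) <= 0.0:
            # inelastic engagement impulse
            vel = model._velocities_at(model.q, model.qd, kin2)
            u2 = attach2 - cable.routing[0]
            u2 /= np.linalg.norm(u2)
            bv_list = [model._velocities_at(model.q, _unit(model.nq, k), kin2)
                       for k in range(model.nq)]
            grad2 = np.array([
                float(np.dot(u2, model.point_velocity(kin2, bv, b, attach2)))
                for bv in bv_list
            ])
            m_mat2 = model._assemble(model.q, model.qd, activations, None)[0]
            minv_g = np.linalg.solve(m_mat2, grad2)
            a_eff = float(grad2 @ minv_g)
            # relative approach speed along the constraint
            c_rel = cable.v + float(grad2 @ model.qd)
            lam = cable.mass * c_rel / (1.0 + cable.mass * a_eff)
            if lam > 0:
                model.qd = model.qd - minv_g * lam
                cable.v = cable.v - lam / cable.mass
            cable.y = cable.free_length(attach2)
            cable.slack = False
    else:
        # taut: reduce the mass onto the arm coordinates
        h = 1e-6
        ldot = float(grad_l @ qd)
        vel_p = model._velocities_at(q + h * qd, qd)
        vel_m = model._velocities_at(q - h * qd, qd)
        kin_p = model.fk(q + h * qd)
        kin_m = model.fk(q - h * qd)
        at_p = model.point_world(kin_p, cable.attach_seg, cable.attach_loc)
        at_m = model.point_world(kin_m, cable.attach_seg, cable.attach_loc)
        up = at_p - cable.routing[0]; up /= np.linalg.norm(up)
        um = at_m - cable.routing[0]; um /= np.linalg.norm(um)
        ldot_p = float(np.dot(up, model.point_velocity(kin_p, vel_p, b, at_p)))
        ldot_m = float(np.dot(um, model.point_velocity(kin_m, vel_m, b, at_m)))
        gamma = (ldot_p - ldot_m) / (2 * h)

        mc = cable.mass
        m_eff = m_mat + mc * np.outer(grad_l, grad_l)
        rhs = q_force - mc * (cable.g + gamma) * grad_l
        qdd = np.linalg.solve(m_eff, rhs)
        tension = mc * (cable.g + float(grad_l @ qdd) + gamma)
        if tension < 0.0:
            tension = 0.0
            cable.slack = True
            qdd = np.linalg.solve(m_mat, q_force)
            model.qd = qd + dt * qdd
            model.q = q + dt * model.qd
            cable.y += cable.v * dt + 0.5 * cable.g * dt * dt
            cable.v += cable.g * dt
        else:
            model.qd = qd + dt * qdd
            model.q = q + dt * model.qd
            kin2 = model.fk(model.q)
            attach2 = model.point_world(kin2, cable.attach_seg, cable.attach_loc)
            cable.y = cable.free_length(attach2)
            cable.v = -float(grad_l @ model.qd)

    model.time += dt
    model.step_count += 1
    if not (np.all(np.isfinite(model.q)) and np.all(np.isfinite(model.qd))):
        raise SimulationDivergedError(model.step_count)
    return tension


def _unit(n: int, k: int) -> np.ndarray:
    e = np.zeros(n)
    e[k] = 1.0
    return e


def run_direction_suite(model_cfg: ModelConfig,
                        controller_cfg: ControllerConfig | None,
                        stp: SpatialTuningPattern | None,
                        exp_cfg: ExperimentConfig,
                        gain_label: str | None = None
                        ) -> dict[str, TrialResult]:
    """One trial per configured loading direction, keyed by label."""
    return {d: run_trial(model_cfg, controller_cfg, stp, d, exp_cfg,
                         gain_label=gain_label)
            for d in exp_cfg.directions}


GAIN_GRID_FACTORS: dict[str, tuple[float, float]] = {
    "Baseline": (1.0, 1.0),
    "PHigh": (1.5, 1.0),
    "PLow": (0.5, 1.0),
    "DHigh": (1.0, 1.5),
    "DLow": (1.0, 0.5),
    "DHighPHigh": (1.5, 1.5),
    "DLowPLow": (0.5, 0.5),
}


def sensitivity_gain_sets(base: GainSet) -> dict[str, GainSet | None]:
    """Seven +/-50% P/D combinations plus the passive model (None)."""
    out: dict[str, GainSet | None] = {
        label: base.scaled(pf, df, label=label)
        for label, (pf, df) in GAIN_GRID_FACTORS.items()
    }
    out["Passive"] = None
    return out


def run_sensitivity(model_cfg: ModelConfig, controller_cfg: ControllerConfig,
                    stp: SpatialTuningPattern, exp_cfg: ExperimentConfig
                    ) -> dict[tuple[str, str], TrialResult]:
    """The full gain grid: 7 gain sets plus passive, each in all eight
    directions (64 runs)."""
    results: dict[tuple[str, str], TrialResult] = {}
    for label, gains in sensitivity_gain_sets(controller_cfg.gains).items():
        if gains is None:
            suite = run_direction_suite(model_cfg, None, None, exp_cfg,
                                        gain_label="Passive")
        else:
            cfg = ControllerConfig(
                gains=gains, apf_delay_ms=controller_cfg.apf_delay_ms,
                mlf_delay_ms=controller_cfg.mlf_delay_ms,
                tau_act_ms=controller_cfg.tau_act_ms,
                tau_deact_ms=controller_cfg.tau_deact_ms,
                mlf_baseline=controller_cfg.mlf_baseline,
                frame_mode=controller_cfg.frame_mode,
                stp_path=controller_cfg.stp_path,
            )
            suite = run_direction_suite(model_cfg, cfg, stp, exp_cfg,
                                        gain_label=label)
        for d, res in suite.items():
            results[(label, d)] = res
    return results
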