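"""Rigid-body shoulder--arm mechanics with Hill-type line muscles.

The arm is a short kinematic tree in minimal coordinates: a torso fixed to
ground, a scapula gliding on the torso through a planar 2-DOF joint (a
stand-in for the scapulothoracic contact), a humerus on a spherical
glenohumeral joint with penalty range stops, and a forearm locked to the
humerus at the configured elbow angle.  Muscles are massless line actuators
routed through via-points; every element of a series chain carries the same
tension, so a muscle contributes the generalized force ``-F dL/dq`` where
``L`` is the full path length.

Equations of motion are assembled by d'Alembert's principle.  Body
velocities are linear in the generalized rates, so the body Jacobians are
obtained exactly by propagating unit rate vectors; the velocity-product
(bias) accelerations are obtained from a central difference of the velocity
field along the current motion.  Time stepping uses fixed-step
semi-implicit Euler (RK4 optional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .config import (
    ConfigurationError,
    HillParams,
    JointSpec,
    ModelConfig,
    MuscleSpec,
)

_FD_H = 1e-6  # s; central-difference step for bias accelerations


class SimulationDivergedError(RuntimeError):
    def __init__(self, step_index: int):
        super().__init__(f"simulation diverged (NaN in state) at step {step_index}")
        self.step_index = step_index


@dataclass
class HillState:
    """Instantaneous state of one muscle: activation ``a`` in [0, 1],
    length ``l`` (m) and lengthening velocity ``v`` (m/s, positive when
    the muscle is being stretched)."""

    activation: float
    length: float
    velocity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.activation <= 1.0:
            raise ValueError("activation must be in [0, 1]")


def hill_force(spec: MuscleSpec, state: HillState,
               hill: HillParams | None = None,
               optimal_length: float | None = None) -> float:
    """Tension (N) of a Hill-type muscle: ``F_max (a fL fV + fP)``.

    ``F_max = pcsa * specific_tension``.  Force-length is a Gaussian of
    width ``fl_width`` about the optimal length; force-velocity is the Hill
    hyperbola on the shortening side (zero at the maximum shortening
    velocity) and a saturating curve on the lengthening side; the passive
    curve is exponential, engaging above the optimal length.  Tension is
    never negative: muscles only pull.
    """
    hill = hill or HillParams()
    l0 = optimal_length if optimal_length is not None else spec.optimal_length
    if l0 is None or l0 <= 0:
        raise ConfigurationError(f"muscle {spec.name}: optimal_length must be positive")
    f_max = spec.pcsa * spec.specific_tension
    lt = state.length / l0
    vt = state.velocity / (hill.v_max * l0)   # lengthening positive, in v_max units
    f_l = math.exp(-(((lt - 1.0) / hill.fl_width) ** 2))
    if vt >= 0.0:
        span = hill.fv_ecc_plateau - 1.0
        f_v = 1.0 + span * vt / (vt + hill.a_rel)
    else:
        v = max(vt, -1.0)
        f_v = (1.0 + v) / (1.0 - v / hill.a_rel)
    f_p = hill.passive_scale * math.expm1(hill.passive_rate * (lt - 1.0)) if lt > 1.0 else 0.0
    f_damp = hill.damping * vt
    return max(0.0, f_max * (state.activation * f_l * f_v + f_p + f_damp))


def chain_forces(tension: float, n_elements: int) -> np.ndarray:
    """Per-element tensions of a series muscle chain: all identical."""
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    return np.full(n_elements, float(tension))


def _rotvec_matrix(rv: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(rv).as_matrix()


def _euler_xyz_matrix(a: float, b: float, c: float) -> np.ndarray:
    return Rotation.from_euler("XYZ", [a, b, c]).as_matrix()


def _euler_xyz_rate_map(a: float, b: float) -> np.ndarray:
    """Columns map intrinsic-XYZ Euler rates to angular velocity in the
    pre-rotation (parent) frame: [e_x, Rx e_y, Rx Ry e_z]."""
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    return np.array([
        [1.0, 0.0, sb],
        [0.0, ca, -sa * cb],
        [0.0, sa, ca * cb],
    ])


@dataclass
class _Body:
    spec_index: int
    parent: int                 # index into bodies, -1 for ground-rooted
    joint: JointSpec | None
    q_slice: slice
    r_fixed: np.ndarray         # fixed rotation offset (locked joints)


@dataclass
class _Kin:
    """Forward-kinematics cache: per-body frame origin, rotation, COM."""
    org: np.ndarray   # (nb, 3)
    rot: np.ndarray   # (nb, 3, 3)
    com: np.ndarray   # (nb, 3)


@dataclass
class _Vel:
    v_org: np.ndarray
    w: np.ndarray
    v_com: np.ndarray


class ArmModel:
    """Assembled kinematic tree with state ``q``, ``qd`` and muscle states."""

    def __init__(self, config: ModelConfig):
        self.config = config
        segs = config.segments
        self._seg_index = {s.name: i for i, s in enumerate(segs)}
        joints_by_child: dict[str, JointSpec] = {}
        for j in config.joints:
            if j.child in joints_by_child:
                raise ConfigurationError(f"segment {j.child} has two parent joints")
            joints_by_child[j.child] = j

        # topological order starting from ground-rooted segments
        self.bodies: list[_Body] = []
        order: list[str] = []
        placed: set[str] = set()
        pending = [s.name for s in segs]
        nq = 0
        guard = 0
        while pending:
            guard += 1
            if guard > 10 * len(segs) + 10:
                raise ConfigurationError("segments do not form a tree rooted at ground")
            name = pending.pop(0)
            j = joints_by_child.get(name)
            parent = "ground" if j is None else j.parent
            if parent != "ground" and parent not in placed:
                pending.append(name)
                continue
            dof = 0 if j is None else j.dof
            r_fixed = np.eye(3)
            if j is not None and j.locked_rotvec is not None:
                r_fixed = _rotvec_matrix(j.locked_rotvec)
            self.bodies.append(_Body(
                spec_index=self._seg_index[name],
                parent=-1 if parent == "ground" else order.index(parent),
                joint=j,
                q_slice=slice(nq, nq + dof),
                r_fixed=r_fixed,
            ))
            order.append(name)
            placed.add(name)
            nq += dof
        self._order = order
        self._body_index = {n: i for i, n in enumerate(order)}
        self.nq = nq
        self.q = np.zeros(nq)
        self.qd = np.zeros(nq)
        self.time = 0.0
        self.step_count = 0
        self.feedforward = np.zeros(nq)

        self._masses = np.array([segs[b.spec_index].mass for b in self.bodies])
        self._inertias = np.stack([segs[b.spec_index].inertia for b in self.bodies])
        self._coms = np.stack([segs[b.spec_index].com_offset for b in self.bodies])

        # muscle routing tables, flattened for vectorized evaluation
        self.muscles = config.muscles
        bidx_all: list[int] = []
        locs_all: list[np.ndarray] = []
        pair_a: list[int] = []
        pair_b: list[int] = []
        pair_m: list[int] = []
        for mi, m in enumerate(self.muscles):
            start = len(bidx_all)
            for seg, p in m.path:
                bidx_all.append(self._body_index[seg])
                locs_all.append(p)
            for k in range(len(m.path) - 1):
                pair_a.append(start + k)
                pair_b.append(start + k + 1)
                pair_m.append(mi)
        self._pt_body = np.array(bidx_all, dtype=int)
        self._pt_loc = (np.stack(locs_all) if locs_all else np.zeros((0, 3)))
        self._pair_a = np.array(pair_a, dtype=int)
        self._pair_b = np.array(pair_b, dtype=int)
        self._pair_m = np.array(pair_m, dtype=int)

        kin = self.fk(self.q)
        self._kin0 = kin
        self.reference_axis = self.humerus_axis(kin)
        self.elbow0 = self.elbow_point(kin)
        self._rest_lengths = self._path_lengths(kin)
        self.optimal_lengths = np.array([
            m.optimal_length if m.optimal_length is not None else self._rest_lengths[i]
            for i, m in enumerate(self.muscles)
        ])
        self.activations = np.zeros(len(self.muscles))
        self.last_tensions = np.zeros(len(self.muscles))

    # ------------------------------------------------------------------ kinematics

    def body_id(self, name: str) -> int:
        try:
            return self._body_index[name]
        except KeyError:
            raise ConfigurationError(f"unknown segment {name!r}") from None

    def fk(self, q: np.ndarray) -> _Kin:
        nb = len(self.bodies)
        org = np.zeros((nb, 3))
        rot = np.zeros((nb, 3, 3))
        for i, b in enumerate(self.bodies):
            if b.parent < 0:
                p_org, p_rot = np.zeros(3), np.eye(3)
            else:
                p_org, p_rot = org[b.parent], rot[b.parent]
            j = b.joint
            if j is None:
                org[i], rot[i] = p_org, p_rot @ b.r_fixed
                continue
            qj = q[b.q_slice]
            if j.kind == "locked":
                org[i] = p_org + p_rot @ j.parent_anchor
                rot[i] = p_rot @ b.r_fixed
            elif j.kind == "planar_2dof":
                org[i] = p_org + p_rot @ (j.parent_anchor + j.axes @ qj)
                rot[i] = p_rot @ b.r_fixed
            else:  # spherical_3dof
                org[i] = p_org + p_rot @ j.parent_anchor
                rot[i] = p_rot @ b.r_fixed @ _euler_xyz_matrix(*qj)
        com = org + np.einsum("nij,nj->ni", rot, self._coms)
        return _Kin(org=org, rot=rot, com=com)

    def _velocities(self, kin: _Kin, qd: np.ndarray) -> _Vel:
        nb = len(self.bodies)
        v = np.zeros((nb, 3))
        w = np.zeros((nb, 3))
        for i, b in enumerate(self.bodies):
            if b.parent < 0:
                pv, pw = np.zeros(3), np.zeros(3)
                p_org, p_rot = np.zeros(3), np.eye(3)
            else:
                pv, pw = v[b.parent], w[b.parent]
                p_org, p_rot = kin.org[b.parent], kin.rot[b.parent]
            j = b.joint
            if j is None or j.kind == "locked":
                r = kin.org[i] - p_org
                v[i] = pv + np.cross(pw, r)
                w[i] = pw
            elif j.kind == "planar_2dof":
                r = kin.org[i] - p_org
                v[i] = pv + np.cross(pw, r) + p_rot @ (j.axes @ qd[b.q_slice])
                w[i] = pw
            else:
                r = kin.org[i] - p_org
                v[i] = pv + np.cross(pw, r)
                qj = self.q[b.q_slice]  # overwritten below for off-state eval
                w[i] = pw + (p_rot @ b.r_fixed) @ (
                    _euler_xyz_rate_map(qj[0], qj[1]) @ qd[b.q_slice]
                )
        v_com = v + np.cross(w, kin.com - kin.org)
        return _Vel(v_org=v, w=w, v_com=v_com)

    def _velocities_at(self, q: np.ndarray, qd: np.ndarray,
                       kin: _Kin | None = None) -> _Vel:
        """Velocity propagation at an arbitrary configuration."""
        kin = kin or self.fk(q)
        saved = self.q
        self.q = q
        try:
            return self._velocities(kin, qd)
        finally:
            self.q = saved

    def point_world(self, kin: _Kin, segment: str, local: np.ndarray) -> np.ndarray:
        i = self.body_id(segment)
        return kin.org[i] + kin.rot[i] @ np.asarray(local, dtype=float)

    def point_velocity(self, kin: _Kin, vel: _Vel, body: int,
                       p_world: np.ndarray) -> np.ndarray:
        return vel.v_org[body] + np.cross(vel.w[body], p_world - kin.org[body])

    def humerus_axis(self, kin: _Kin | None = None) -> np.ndarray:
        """Unit vector from the proximal to the distal end of the humerus."""
        kin = kin or self.fk(self.q)
        ax = kin.rot[self.body_id("humerus")][:, 0]
        n = np.linalg.norm(ax)
        if n < 1e-12:
            raise ConfigurationError("degenerate humerus axis")
        return ax / n

    def elbow_point(self, kin: _Kin | None = None) -> np.ndarray:
        kin = kin or self.fk(self.q)
        return self.point_world(kin, "forearm", np.zeros(3))

    # ------------------------------------------------------------------ muscles

    def _muscle_world_points(self, kin: _Kin) -> np.ndarray:
        if self._pt_body.size == 0:
            return np.zeros((0, 3))
        return kin.org[self._pt_body] + np.einsum(
            "nij,nj->ni", kin.rot[self._pt_body], self._pt_loc
        )

    def _segment_units(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        seg = pts[self._pair_b] - pts[self._pair_a]
        ln = np.linalg.norm(seg, axis=1)
        safe = np.where(ln < 1e-12, 1e-12, ln)
        return seg / safe[:, None], ln

    def _path_lengths(self, kin: _Kin, pts: np.ndarray | None = None) -> np.ndarray:
        out = np.zeros(len(self.muscles))
        if self._pair_m.size == 0:
            return out
        if pts is None:
            pts = self._muscle_world_points(kin)
        _, ln = self._segment_units(pts)
        np.add.at(out, self._pair_m, ln)
        return out

    def path_length(self, muscle: str, kin: _Kin | None = None) -> float:
        """Total path length (m) through all via-points in the current pose."""
        kin = kin or self.fk(self.q)
        for i, m in enumerate(self.muscles):
            if m.name == muscle:
                return float(self._path_lengths(kin)[i])
        raise ConfigurationError(f"unknown muscle {muscle!r}")

    def muscle_lengths(self) -> np.ndarray:
        return self._path_lengths(self.fk(self.q))

    def muscle_rest_lengths(self) -> np.ndarray:
        return self._rest_lengths.copy()

    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    def _muscle_rates(self, kin: _Kin, vel: _Vel,
                      pts: np.ndarray | None = None,
                      units: np.ndarray | None = None) -> np.ndarray:
        """dL/dt for every muscle under the body velocity field ``vel``."""
        rates = np.zeros(len(self.muscles))
        if self._pair_m.size == 0:
            return rates
        if pts is None:
            pts = self._muscle_world_points(kin)
        if units is None:
            units, _ = self._segment_units(pts)
        bi = self._pt_body
        v_pts = vel.v_org[bi] + np.cross(vel.w[bi], pts - kin.org[bi])
        dv = v_pts[self._pair_b] - v_pts[self._pair_a]
        np.add.at(rates, self._pair_m, np.einsum("ki,ki->k", units, dv))
        return rates

    # ------------------------------------------------------------------ dynamics

    def _joint_space_forces(self, q: np.ndarray, qd: np.ndarray) -> np.ndarray:
        tau = np.zeros(self.nq)
        for b in self.bodies:
            j = b.joint
            if j is None or j.dof == 0:
                continue
            sl = b.q_slice
            tau[sl] -= j.viscous_damping * qd[sl]
            if j.centering_stiffness or j.centering_damping:
                tau[sl] -= j.centering_stiffness * q[sl] + j.centering_damping * qd[sl]
            if j.rotation_limits is not None and j.stop_stiffness:
                for k, (lo, hi) in enumerate(j.rotation_limits):
                    qi, qdi = q[sl][k], qd[sl][k]
                    if qi < lo:
                        tau[sl.start + k] += j.stop_stiffness * (lo - qi) - j.stop_damping * qdi
                    elif qi > hi:
                        tau[sl.start + k] += j.stop_stiffness * (hi - qi) - j.stop_damping * qdi
        return tau

    def _assemble(self, q: np.ndarray, qd: np.ndarray, activations: np.ndarray,
                  point_forces: list[tuple[str, np.ndarray, np.ndarray]] | None = None):
        """Mass matrix, generalized force, and cable-coupling geometry.

        Returns (M, Q, lengths, dLdq, tensions); the caller adds cable
        coupling and solves.
        """
        nb, nq = len(self.bodies), self.nq
        kin = self.fk(q)
        vel = self._velocities_at(q, qd, kin)

        # exact Jacobians: velocity field under unit rates
        jv = np.zeros((nb, nq, 3))
        jw = np.zeros((nb, nq, 3))
        basis_vels = []
        for k in range(nq):
            e = np.zeros(nq)
            e[k] = 1.0
            bv = self._velocities_at(q, e, kin)
            basis_vels.append(bv)
            jv[:, k, :] = bv.v_com
            jw[:, k, :] = bv.w

        # bias (velocity-product) accelerations by central difference in time
        vel_p = self._velocities_at(q + _FD_H * qd, qd)
        vel_m = self._velocities_at(q - _FD_H * qd, qd)
        a_bias = (vel_p.v_com - vel_m.v_com) / (2 * _FD_H)
        w_bias = (vel_p.w - vel_m.w) / (2 * _FD_H)

        iw = np.einsum("nij,njk,nlk->nil", kin.rot, self._inertias, kin.rot)

        m_mat = (
            np.einsum("n,nki,nji->nkj", self._masses, jv, jv)
            + np.einsum("nki,nil,njl->nkj", jw, iw, jw)
        ).sum(axis=0)

        grav = np.array([0.0, 0.0, -self.config.gravity])
        gyro = np.cross(vel.w, np.einsum("nij,nj->ni", iw, vel.w))
        q_force = (
            np.einsum("nki,ni->k", jv, self._masses[:, None] * (grav - a_bias))
            - np.einsum("nki,ni->k", jw,
                        np.einsum("nij,nj->ni", iw, w_bias) + gyro)
        )
        q_force += self._joint_space_forces(q, qd)
        q_force += self.feedforward

        # muscle tensions and generalized forces
        pts = self._muscle_world_points(kin)
        units = self._segment_units(pts)[0] if self._pair_m.size else None
        lengths = self._path_lengths(kin, pts)
        rates = self._muscle_rates(kin, vel, pts, units)
        tensions = np.zeros(len(self.muscles))
        dldq = np.zeros((len(self.muscles), nq))
        if self.muscles:
            for k in range(nq):
                dldq[:, k] = self._muscle_rates(kin, basis_vels[k], pts, units)
            for mi, m in enumerate(self.muscles):
                st = HillState(activation=float(np.clip(activations[mi], 0, 1)),
                               length=lengths[mi], velocity=rates[mi])
                tensions[mi] = hill_force(m, st, self.config.hill,
                                          optimal_length=self.optimal_lengths[mi])
            q_force -= tensions @ dldq

        # external point forces (world frame) applied at body-fixed points
        if point_forces:
            for seg, local, f in point_forces:
                b = self.body_id(seg)
                pw = self.point_world(kin, seg, np.asarray(local, dtype=float))
                for k in range(nq):
                    vp = self.point_velocity(kin, basis_vels[k], b, pw)
                    q_force[k] += float(np.dot(f, vp))

        return m_mat, q_force, kin, basis_vels, lengths, dldq, tensions

    def accelerations(self, activations: np.ndarray | None = None,
                      point_forces=None) -> np.ndarray:
        a = self.activations if activations is None else np.asarray(activations, float)
        m_mat, q_force, *_ , tensions = self._assemble(self.q, self.qd, a, point_forces)
        self.last_tensions = tensions
        return np.linalg.solve(m_mat, q_force)

    def step(self, dt: float, activations: np.ndarray | None = None,
             point_forces=None) -> None:
        """Advance one fixed step (semi-implicit Euler on the arm)."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if activations is not None:
            self.activations = np.asarray(activations, dtype=float)
        if self.config.integrator == "rk4":
            self._rk4_step(dt, point_forces)
        else:
            qdd = self.accelerations(self.activations, point_forces)
            self.qd = self.qd + dt * qdd
            self.q = self.q + dt * self.qd
        self.time += dt
        self.step_count += 1
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qd))):
            raise SimulationDivergedError(self.step_count)

    def _rk4_step(self, dt: float, point_forces) -> None:
        def deriv(q, qd):
            m_mat, q_force, *_ = self._assemble(q, qd, self.activations, point_forces)
            return qd, np.linalg.solve(m_mat, q_force)

        q0, qd0 = self.q, self.qd
        k1q, k1v = deriv(q0, qd0)
        k2q, k2v = deriv(q0 + 0.5 * dt * k1q, qd0 + 0.5 * dt * k1v)
        k3q, k3v = deriv(q0 + 0.5 * dt * k2q, qd0 + 0.5 * dt * k2v)
        k4q, k4v = deriv(q0 + dt * k3q, qd0 + dt * k3v)
        self.q = q0 + dt / 6 * (k1q + 2 * k2q + 2 * k3q + k4q)
        self.qd = qd0 + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)

    # ------------------------------------------------------------------ helpers

    def set_feedforward(self, activations: np.ndarray | None = None) -> None:
        """Constant generalized force holding the initial posture.

        Computed once at the build pose as the negative of the static
        generalized force (gravity plus tonic muscle force at rest), it
        stands in for the postural support a seated torso provides.
        """
        if not self.config.gravity_compensation:
            self.feedforward = np.zeros(self.nq)
            return
        a = np.zeros(len(self.muscles)) if activations is None else np.asarray(activations, float)
        self.feedforward = np.zeros(self.nq)
        _, q_force, *_ = self._assemble(self.q, np.zeros(self.nq), a, None)
        self.feedforward = -q_force

    def mechanical_energy(self) -> float:
        """Kinetic plus gravitational potential energy of the linkage."""
        kin = self.fk(self.q)
        vel = self._velocities_at(self.q, self.qd, kin)
        iw = np.einsum("nij,njk,nlk->nil", kin.rot, self._inertias, kin.rot)
        ke = 0.5 * float(
            np.sum(self._masses * np.einsum("ni,ni->n", vel.v_com, vel.v_com))
            + np.einsum("ni,nij,nj->", vel.w, iw, vel.w)
        )
        pe = float(np.sum(self._masses * self.config.gravity * kin.com[:, 2]))
        return ke + pe

    def dof_summary(self) -> dict[str, int]:
        out = {}
        for b in self.bodies:
            if b.joint is not None:
                out[b.joint.name] = b.joint.dof
        return out


def build_arm_model(config: ModelConfig) -> ArmModel:
    """Assemble the arm: torso fixed to ground, scapula planar,
    glenohumeral spherical, elbow locked at the configured angle."""
    return ArmModel(config)


def step_dynamics(model: ArmModel, external_forces=None, dt: float = 1e-3,
                  activations: np.ndarray | None = None) -> ArmModel:
    """Advance the model one fixed step; mutates and returns ``model``.

    ``external_forces`` is a list of (segment, local point, world force)
    triples.
    """
    model.step(dt, activations=activations, point_forces=external_forces)
    return model


def isolated_activation_direction(model: ArmModel, muscle: str,
                                  level: float = 0.5, duration: float = 0.15,
                                  dt: float = 1e-3) -> float:
    """Run the muscle-routing check: activate one muscle alone and return
    the polar direction (rad, from +Y toward +Z) of the resulting elbow
    motion in the plane perpendicular to the initial humerus axis."""
    names = model.muscle_names()
    if muscle not in names:
        raise ConfigurationError(f"unknown muscle {muscle!r}")
    act = np.zeros(len(names))
    act[names.index(muscle)] = level
    model.set_feedforward()
    n = int(round(duration / dt))
    for _ in range(n):
        model.step(dt, activations=act)
    disp = model.elbow_point() - model.elbow0
    axis = model.reference_axis
    planar = disp - np.dot(disp, axis) * axis
    # evaluation-plane basis: Y lateral, Z completing right-handed
    y_axis = np.array([0.0, 1.0, 0.0]) - axis[1] * axis
    y_axis /= np.linalg.norm(y_axis)
    z_axis = np.cross(axis, y_axis)
    return math.atan2(float(np.dot(planar, z_axis)), float(np.dot(planar, y_axis)))
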