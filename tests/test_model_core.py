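import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shoulderctl.config import ConfigurationError, HillParams, MuscleSpec, load_config
from shoulderctl.model import (
    HillState,
    build_arm_model,
    chain_forces,
    hill_force,
    isolated_activation_direction,
    step_dynamics,
)

SPEC = MuscleSpec(name="m", pcsa=10.0,
                  path=[("torso", np.zeros(3)), ("humerus", np.zeros(3))],
                  optimal_length=0.1)


def test_hill_isometric_maximal():
    # a=1, l=l0, v=0: F = F_max exactly (fL=1, fV=1, no passive, no damping)
    f = hill_force(SPEC, HillState(1.0, 0.1, 0.0))
    assert f == pytest.approx(10.0 * 50.0)


def test_hill_passive_only_at_rest_is_zero():
    assert hill_force(SPEC, HillState(0.0, 0.1, 0.0)) == 0.0


def test_hill_passive_engages_on_stretch():
    hp = HillParams()  # class defaults, not the bundled calibrated values
    f = hill_force(SPEC, HillState(0.0, 0.12, 0.0), hill=hp)
    expected = 500.0 * hp.passive_scale * math.expm1(hp.passive_rate * 0.2)
    assert f == pytest.approx(expected, rel=1e-12)


def test_hill_max_shortening_velocity_kills_active_force():
    hp = HillParams(damping=0.0, passive_scale=0.0)
    f = hill_force(SPEC, HillState(1.0, 0.1, -1.0), hill=hp)  # v = -v_max
    assert f == 0.0


def test_hill_eccentric_plateau():
    hp = HillParams(damping=0.0, passive_scale=0.0)
    slow = hill_force(SPEC, HillState(1.0, 0.1, 0.05), hill=hp)
    fast = hill_force(SPEC, HillState(1.0, 0.1, 50.0), hill=hp)
    assert 500.0 < slow < fast < 500.0 * 1.5 + 1e-9


@given(st.floats(0.0, 1.0), st.floats(0.05, 0.2), st.floats(-2.0, 2.0))
def test_hill_force_never_negative(a, l, v):
    assert hill_force(SPEC, HillState(a, l, v)) >= 0.0


def test_chain_forces_uniform():
    np.testing.assert_array_equal(chain_forces(12.5, 3), [12.5, 12.5, 12.5])
    with pytest.raises(ValueError):
        chain_forces(1.0, 0)


def test_model_topology(config):
    model = build_arm_model(config.model)
    assert model.nq == 5
    assert model.dof_summary() == {"scapulothoracic": 2, "glenohumeral": 3,
                                   "elbow": 0}
    assert len(model.muscle_names()) == 15


def test_mass_matrix_spd(config, rng):
    model = build_arm_model(config.model)
    for _ in range(5):
        q = rng.uniform(-0.3, 0.3, 5)
        qd = rng.uniform(-1.0, 1.0, 5)
        m_mat = model._assemble(q, qd, np.zeros(15), None)[0]
        np.testing.assert_allclose(m_mat, m_mat.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(m_mat) > 0)


def test_muscle_rate_matches_length_derivative(config, rng):
    # dL/dt from the velocity field must equal the finite difference of the
    # path length along the motion
    model = build_arm_model(config.model)
    q = rng.uniform(-0.2, 0.2, 5)
    qd = rng.uniform(-1.0, 1.0, 5)
    kin = model.fk(q)
    vel = model._velocities_at(q, qd, kin)
    rates = model._muscle_rates(kin, vel)
    h = 1e-7
    lp = model._path_lengths(model.fk(q + h * qd))
    lm = model._path_lengths(model.fk(q - h * qd))
    np.testing.assert_allclose(rates, (lp - lm) / (2 * h), rtol=1e-5, atol=1e-8)


def test_gravity_compensation_holds_posture(config):
    model = build_arm_model(config.model)
    model.set_feedforward()
    for _ in range(100):
        step_dynamics(model, dt=1e-3)
    assert np.linalg.norm(model.elbow_point() - model.elbow0) < 1e-9


def test_divergence_detection(config):
    from shoulderctl.model import SimulationDivergedError
    model = build_arm_model(config.model)
    model.qd[:] = np.nan
    with pytest.raises(SimulationDivergedError):
        model.step(1e-3)


def test_unknown_muscle_raises(config):
    model = build_arm_model(config.model)
    with pytest.raises(ConfigurationError):
        model.path_length("not_a_muscle")


@pytest.mark.parametrize("muscle", [
    "ant_deltoid", "mid_deltoid", "post_deltoid", "pect_major_clav",
    "pect_major_stern", "latissimus_dorsi", "infraspinatus",
    "biceps_brachii", "triceps_brachii",
])
def test_isolated_activation_matches_action_direction(config, muscle):
    # routing check: each APF muscle, activated alone, moves the elbow in
    # its configured anatomical action direction
    spec = next(m for m in config.model.muscles if m.name == muscle)
    model = build_arm_model(config.model)
    phi = isolated_activation_direction(model, muscle)
    err = math.degrees(abs(math.atan2(math.sin(phi - math.radians(spec.action_phi_deg)),
                                      math.cos(phi - math.radians(spec.action_phi_deg)))))
    assert err < 15.0
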