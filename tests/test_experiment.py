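import dataclasses
import math

import numpy as np
import pytest

from shoulderctl.config import ConfigurationError, GainSet
from shoulderctl.experiment import (
    Cable,
    GAIN_GRID_FACTORS,
    cable_tension_and_force,
    run_trial,
    sensitivity_gain_sets,
)
from shoulderctl.model import build_arm_model


def test_static_tension_is_weight():
    tension, force = cable_tension_and_force((8.0, 0.0, False),
                                             [[0.0, 0.0, 1.5]],
                                             [0.0, 0.0, 0.0])
    assert tension == pytest.approx(8.0 * 9.81)
    np.testing.assert_allclose(force, [0.0, 0.0, tension], atol=1e-12)


def test_slack_cable_carries_nothing():
    tension, force = cable_tension_and_force((8.0, 3.0, True),
                                             [[1.0, 0.0, 0.0]], [0.0, 0.0, 0.0])
    assert tension == 0.0
    np.testing.assert_allclose(force, 0.0)


def test_free_fall_reduces_tension():
    tension, _ = cable_tension_and_force((8.0, 9.81, False),
                                         [[1.0, 0.0, 0.0]], [0.0, 0.0, 0.0])
    assert tension == pytest.approx(0.0, abs=1e-12)


def test_degenerate_routing_raises():
    with pytest.raises(ConfigurationError):
        cable_tension_and_force((8.0, 0.0, False), [[0.0, 0.0, 0.0]],
                                [0.0, 0.0, 0.0])


def test_cable_geometry(config):
    model = build_arm_model(config.model)
    cable = Cable(model, "abduction", config.experiment)
    # the routing point sits 1.5 m from the elbow along +Y (abduction)
    np.testing.assert_allclose(cable.routing[0] - model.elbow0,
                               [0.0, 1.5, 0.0], atol=1e-9)
    assert cable.l0 == pytest.approx(1.5)
    assert cable.slack and cable.v == pytest.approx(0.77)


def test_unknown_direction_rejected(config):
    with pytest.raises(ConfigurationError):
        run_trial(config.model, None, None, "sideways", config.experiment)


def test_passive_trial_is_deterministic(config):
    exp = dataclasses.replace(config.experiment, duration=0.2)
    r1 = run_trial(config.model, None, None, "extension", exp)
    r2 = run_trial(config.model, None, None, "extension", exp)
    np.testing.assert_array_equal(r1.elbow, r2.elbow)
    np.testing.assert_array_equal(r1.tension, r2.tension)


def test_trial_invariants(config):
    exp = dataclasses.replace(config.experiment, duration=0.4)
    res = run_trial(config.model, None, None, "flexion", exp)
    assert np.all(res.tension >= 0.0)
    assert np.all(np.isfinite(res.elbow))
    assert 0.0 < res.peak_theta() < math.pi
    # the load moves the elbow predominantly in the loading direction
    i = int(np.argmax(np.abs(res.theta)))
    assert abs(math.degrees(res.phi[i]) - 90.0) < 30.0


def test_controller_transparency(config, default_stp):
    # zero gains and zero baselines: the active machinery must reproduce
    # the passive trajectory exactly
    exp = dataclasses.replace(config.experiment, duration=0.3)
    zero = dataclasses.replace(
        config.controller,
        gains=GainSet(0.0, 0.0, 0.0, 0.0, label="Zero"),
        mlf_baseline=0.0,
    )
    from shoulderctl.stp import SpatialTuningPattern
    stp0 = SpatialTuningPattern(default_stp.weights.copy(),
                                default_stp.baseline * 0.0,
                                default_stp.window_ms)
    passive = run_trial(config.model, None, None, "adduction", exp)
    active = run_trial(config.model, zero, stp0, "adduction", exp)
    np.testing.assert_allclose(active.elbow, passive.elbow, atol=1e-12)
    assert np.all(active.activations == 0.0)


def test_gain_grid_composition():
    sets = sensitivity_gain_sets(GainSet())
    assert set(sets) == set(GAIN_GRID_FACTORS) | {"Passive"}
    assert sets["Passive"] is None
    assert sets["PHigh"].p_apf == pytest.approx(1.6 * 1.5)
    assert sets["DLow"].d_apf == pytest.approx(150.0 * 0.5)
    assert sets["DHighPHigh"].p_apf == pytest.approx(2.4)
    assert sets["DHighPHigh"].d_apf == pytest.approx(225.0)
    # MLF gains are not part of the grid
    assert sets["PHigh"].p_mlf == pytest.approx(0.5)


def test_engagement_removes_relative_velocity(config):
    # immediately after engagement the mass and cable move together: the
    # tension trace starts positive and stays finite
    exp = dataclasses.replace(config.experiment, duration=0.05)
    res = run_trial(config.model, None, None, "extension", exp)
    engaged = np.nonzero(res.tension > 0)[0]
    assert len(engaged) > 0 and engaged[0] <= 2
    assert res.tension.max() < 8.0 * 9.81 * 5
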