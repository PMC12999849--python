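import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shoulderctl.evaluation import (
    EvaluationError,
    PeakStats,
    PlanarTrace,
    circular_mean,
    peak_and_ttp,
    polar_ensemble_average,
    project_to_plane,
    sd_ellipse,
    within_one_sd,
)


def test_projection_removes_axis_component():
    axis = np.array([1.0, 0.0, 0.0])
    traj = np.array([[0.0, 0.0, 0.0],
                     [0.5, 0.001, 0.002],   # mostly along the axis
                     [0.1, 0.003, -0.001]])
    tr = project_to_plane(traj, axis)
    np.testing.assert_allclose(tr.xy[0], [0.0, 0.0])
    np.testing.assert_allclose(tr.xy[1], [1.0, 2.0], atol=1e-9)   # mm
    np.testing.assert_allclose(tr.xy[2], [3.0, -1.0], atol=1e-9)


def test_projection_tilted_axis():
    axis = np.array([0.0, 0.0, 1.0])  # plane is the XY plane; Y lateral
    traj = np.array([[0.0, 0.0, 0.0], [0.0, 0.01, 5.0]])
    tr = project_to_plane(traj, axis)
    assert tr.magnitude[1] == pytest.approx(10.0)


def test_circular_mean_wraps():
    angles = np.array([math.radians(350.0), math.radians(10.0)])
    assert circular_mean(angles) == pytest.approx(0.0, abs=1e-12)


def test_polar_average_of_identical_traces():
    t = np.linspace(0, 1, 101)
    xy = np.column_stack([np.sin(3 * t), np.cos(3 * t)]) * 10
    tr = PlanarTrace(t, xy)
    avg = polar_ensemble_average([tr, tr, tr])
    np.testing.assert_allclose(avg.magnitude,
                               tr.resampled(avg.time).magnitude, atol=1e-9)


def test_polar_average_combines_magnitude_and_direction():
    t = np.array([0.0, 1.0])
    a = PlanarTrace(t, np.array([[1.0, 0.0], [2.0, 0.0]]))
    b = PlanarTrace(t, np.array([[0.0, 1.0], [0.0, 4.0]]))
    avg = polar_ensemble_average([a, b], dt=1.0)
    # mean magnitude 3, circular mean direction 45 deg
    np.testing.assert_allclose(avg.magnitude[-1], 3.0)
    assert math.degrees(avg.direction[-1]) == pytest.approx(45.0)


def test_sd_ellipse_known_covariance():
    pts = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    ell = sd_ellipse(pts)
    # sample covariance (ddof=1): diag(8/3, 2/3)
    assert ell.semi_axes[0] == pytest.approx(math.sqrt(8 / 3))
    assert ell.semi_axes[1] == pytest.approx(math.sqrt(2 / 3))
    assert abs(math.cos(ell.orientation)) == pytest.approx(1.0)
    assert ell.area == pytest.approx(math.pi * math.sqrt(8 / 3) * math.sqrt(2 / 3))


def test_sd_ellipse_needs_three_points():
    with pytest.raises(EvaluationError):
        sd_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]))


def _make_traces(rng, n=6, m=201):
    t = np.linspace(0, 1, m)
    out = []
    for _ in range(n):
        peak = rng.uniform(50, 250)
        ttp = rng.uniform(0.1, 0.7)
        r = peak * np.exp(-((t - ttp) / 0.2) ** 2)
        phi = rng.uniform(0, 2 * math.pi)
        out.append(PlanarTrace(t, np.column_stack([r * math.cos(phi),
                                                   r * math.sin(phi)])))
    return out


@given(st.integers(0, 10_000))
def test_peak_of_average_not_larger_than_average_of_peaks(seed):
    rng = np.random.default_rng(seed)
    traces = _make_traces(rng)
    pa = peak_and_ttp(traces, "peak_of_average", window_ms=1000.0)
    ap = peak_and_ttp(traces, "average_of_peaks", window_ms=1000.0)
    assert pa.peak <= ap.peak + 1e-9
    assert ap.peak_sd is not None and ap.peak_sd >= 0


def test_window_excludes_late_peak():
    t = np.linspace(0, 1, 1001)
    r = np.where(t > 0.9, 100.0, t * 10)
    tr = PlanarTrace(t, np.column_stack([r, np.zeros_like(r)]))
    st_ = peak_and_ttp([tr], "peak_of_average", window_ms=800.0)
    assert st_.peak == pytest.approx(8.0)
    assert st_.ttp == pytest.approx(0.8)


def test_ttp_earliest_maximum():
    t = np.linspace(0, 1, 101)
    r = np.zeros_like(t)
    r[30] = r[60] = 5.0
    tr = PlanarTrace(t, np.column_stack([r, np.zeros_like(r)]))
    st_ = peak_and_ttp([tr], "average_of_peaks", window_ms=1000.0)
    assert st_.ttp == pytest.approx(0.3)


def test_unknown_method_rejected():
    with pytest.raises(EvaluationError):
        peak_and_ttp([PlanarTrace([0, 1], np.zeros((2, 2)))], "median")


def test_within_one_sd_closed_interval():
    ens = PeakStats("average_of_peaks", peak=100.0, ttp=0.2, peak_sd=20.0)
    assert within_one_sd(120.0, ens)
    assert within_one_sd(80.0, ens)
    assert not within_one_sd(121.0, ens)
    with pytest.raises(EvaluationError):
        within_one_sd(1.0, PeakStats("peak_of_average", 1.0, 0.1))
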