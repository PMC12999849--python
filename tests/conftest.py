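import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    from shoulderctl.config import load_config
    return load_config()


@pytest.fixture(scope="session")
def default_stp():
    from importlib import resources
    from shoulderctl.stp import SpatialTuningPattern
    path = resources.files("shoulderctl") / "data" / "default_stp.tsv"
    return SpatialTuningPattern.from_tsv(str(path))


@pytest.fixture(scope="session")
def sensitivity_grid(config, default_stp):
    """The full 64-trial gain grid, shared across the acceptance tests."""
    from shoulderctl.experiment import run_sensitivity
    return run_sensitivity(config.model, config.controller, default_stp,
                           config.experiment)


@pytest.fixture(scope="session")
def planar_peaks(sensitivity_grid, config):
    """(label, direction) -> (peak_mm, ttp_s) in the evaluation plane."""
    from shoulderctl.evaluation import peak_and_ttp, project_to_plane
    out = {}
    for key, res in sensitivity_grid.items():
        tr = project_to_plane(res.elbow, res.reference_axis, time=res.time)
        st = peak_and_ttp([tr], "peak_of_average",
                          window_ms=config.evaluation.window_ms)
        out[key] = (st.peak, st.ttp)
    return out


@pytest.fixture(scope="session")
def small_emg():
    """A reduced noise-free synthetic EMG set for fast STP tests."""
    from shoulderctl.synth import EmgFixtureParams, generate_emg
    params = EmgFixtureParams(n_subjects=3, noise_sd=0.0, seed=7,
                              pre_s=0.6, post_s=1.2)
    return params, generate_emg(params)


def rand_state(rng, scale=0.3):
    q = rng.uniform(-scale, scale, 5)
    qd = rng.uniform(-1.0, 1.0, 5)
    return q, qd


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
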