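import numpy as np
import pytest

from shoulderctl.config import DIRECTIONS
from shoulderctl.stp import (
    BiarticularRatios,
    EmgRecording,
    MvicTable,
    StpError,
    WINDOW_PRESETS,
    apply_biarticular_ratio,
    build_stp,
    extract_baseline,
    extract_peak,
    normalize_emg,
    read_emg_long,
    read_mvic,
    rescale_for_controller,
    write_emg_long,
    write_mvic,
)


def _rec(samples, sr=100.0, onset=0.5, subject="S01", muscle="m",
         direction="flexion"):
    return EmgRecording(subject=subject, muscle=muscle, direction=direction,
                        samples=np.asarray(samples, float), sample_rate=sr,
                        loading_onset=onset)


def test_window_presets():
    assert WINDOW_PRESETS == {"methods": 1000.0, "limitations": 500.0}


def test_normalize_divides_by_mvic():
    rec = _rec(np.ones(100) * 2.0)
    mvic = MvicTable({("S01", "m"): 4.0})
    out = normalize_emg(rec, mvic)
    np.testing.assert_allclose(out.samples, 0.5)


def test_extract_peak_window_is_inclusive():
    # onset at sample 50 (0.5 s, 100 Hz); peak at exactly onset + window
    samples = np.zeros(200)
    samples[150] = 3.0  # 1000 ms after onset
    rec = _rec(samples)
    assert extract_peak(rec, window_ms=1000.0) == 3.0
    samples2 = np.zeros(200)
    samples2[151] = 3.0
    assert extract_peak(_rec(samples2), window_ms=1000.0) == 0.0


def test_extract_peak_window_too_long_raises():
    with pytest.raises(StpError):
        extract_peak(_rec(np.zeros(100)), window_ms=1000.0)


def test_extract_baseline_pre_window():
    samples = np.concatenate([np.full(50, 0.2), np.full(50, 0.9)])
    assert extract_baseline(_rec(samples), pre_window_ms=500.0) == pytest.approx(0.2)


def test_biarticular_ratios_exact():
    r = BiarticularRatios()
    assert r.biceps_ratio == 1.56
    assert r.triceps_ratio == 1.82
    np.testing.assert_allclose(apply_biarticular_ratio([1.56], "biceps_brachii"),
                               [1.0])
    np.testing.assert_allclose(apply_biarticular_ratio([1.82], "triceps_brachii"),
                               [1.0])
    np.testing.assert_allclose(apply_biarticular_ratio([0.7], "ant_deltoid"),
                               [0.7])


def test_build_stp_recovers_noise_free_truth(small_emg):
    params, (recs, mvic, truth) = small_emg
    stp = build_stp(recs, mvic, window_ms=1000.0)
    for d in DIRECTIONS:
        np.testing.assert_allclose(stp.weights[d].to_numpy(),
                                   truth[d].to_numpy(), atol=1e-9)
    np.testing.assert_allclose(stp.baseline.to_numpy(),
                               truth["baseline"].to_numpy(), atol=1e-9)


def test_build_stp_missing_cell_raises(small_emg):
    _, (recs, mvic, _) = small_emg
    partial = [r for r in recs if r.direction != "adduction"]
    with pytest.raises(StpError, match="adduction"):
        build_stp(partial, mvic)


def test_build_stp_subject_filter(small_emg):
    _, (recs, mvic, truth) = small_emg
    stp = build_stp(recs, mvic, subjects=["S01"])
    # noise-free generator: every subject yields the same normalized table
    np.testing.assert_allclose(stp.weights["flexion"].to_numpy(),
                               truth["flexion"].to_numpy(), atol=1e-9)


def test_rescale_for_controller_column_max_one(small_emg):
    _, (recs, mvic, _) = small_emg
    stp = build_stp(recs, mvic)
    apf = ["ant_deltoid", "mid_deltoid", "post_deltoid", "latissimus_dorsi"]
    out = rescale_for_controller(stp, apf)
    np.testing.assert_allclose(out.weights.max(axis=0).to_numpy(), 1.0,
                               atol=1e-12)
    with pytest.raises(StpError):
        rescale_for_controller(stp, ["not_present"])


def test_stp_tsv_roundtrip(small_emg, tmp_path):
    _, (recs, mvic, _) = small_emg
    stp = build_stp(recs, mvic, window_ms=500.0)
    path = tmp_path / "stp.tsv"
    stp.to_tsv(path)
    back = type(stp).from_tsv(path)
    np.testing.assert_allclose(back.weights.to_numpy(), stp.weights.to_numpy(),
                               atol=1e-9)
    assert back.window_ms == 500.0


def test_emg_and_mvic_io_roundtrip(small_emg, tmp_path):
    _, (recs, mvic, _) = small_emg
    sub = recs[:5]
    write_emg_long(sub, tmp_path / "emg.tsv")
    write_mvic(mvic, tmp_path / "mvic.tsv")
    recs2 = read_emg_long(tmp_path / "emg.tsv")
    mvic2 = read_mvic(tmp_path / "mvic.tsv")
    assert len(recs2) == 5
    np.testing.assert_allclose(recs2[0].samples, sub[0].samples, atol=1e-9)
    assert recs2[0].subject == sub[0].subject
    assert mvic2.get(sub[0].subject, sub[0].muscle) == pytest.approx(
        mvic.get(sub[0].subject, sub[0].muscle))


def test_negative_samples_rejected():
    with pytest.raises((StpError, ValueError)):
        _rec(np.array([-0.1, 0.2, 0.3]))
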