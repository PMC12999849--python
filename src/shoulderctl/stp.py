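"""Spatial tuning patterns (STPs) from MVIC-normalized EMG.

An STP is a muscle x loading-direction table of normalized peak activities,
used by the shoulder controller to distribute a scalar command across
muscles, together with a per-muscle baseline activity level taken from the
pre-loading portion of the recordings.

The construction pipeline mirrors the volunteer-data workflow: normalize
each recording by the subject's MVIC, take the peak within a window after
loading onset (1,000 ms default; a 500 ms "reflex" preset is also provided),
rescale the bi-articular elbow muscles by their shoulder/elbow MVIC ratios,
average across subjects, and finally rescale each direction column by its
maximum over the muscles included in the controller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import DIRECTIONS, ConfigurationError

# peak-extraction window presets (ms after loading onset)
WINDOW_PRESETS = {"methods": 1000.0, "limitations": 500.0}


class StpError(ValueError):
    """Raised for EMG normalization or STP construction problems."""


@dataclass
class EmgRecording:
    """One rectified/enveloped EMG trace for subject x muscle x direction."""

    subject: str
    muscle: str
    direction: str
    samples: np.ndarray        # arbitrary units (raw) or fractions (normalized)
    sample_rate: float         # Hz
    loading_onset: float       # s from recording start

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < 0):
            raise StpError(f"{self.subject}/{self.muscle}: negative EMG samples")
        if not 0.0 <= self.loading_onset <= len(self.samples) / self.sample_rate:
            raise StpError(f"{self.subject}/{self.muscle}: onset outside recording")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


class MvicTable:
    """Per-subject, per-muscle maximum voluntary isometric contraction."""

    def __init__(self, values: dict[tuple[str, str], float]):
        for (s, m), v in values.items():
            if v <= 0:
                raise StpError(f"MVIC for {s}/{m} must be > 0")
        self._values = dict(values)

    def get(self, subject: str, muscle: str) -> float:
        try:
            return self._values[(subject, muscle)]
        except KeyError:
            raise StpError(f"missing MVIC entry for {subject}/{muscle}") from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MvicTable":
        return cls({(str(r.subject), str(r.muscle)): float(r.value)
                    for r in df.itertuples()})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, m, v) for (s, m), v in self._values.items()],
            columns=["subject", "muscle", "value"],
        )


@dataclass
class BiarticularRatios:
    """Shoulder/elbow MVIC activity ratios for the elbow prime movers."""

    biceps_ratio: float = 1.56
    triceps_ratio: float = 1.82

    def __post_init__(self) -> None:
        if self.biceps_ratio <= 0 or self.triceps_ratio <= 0:
            raise StpError("bi-articular ratios must be > 0")


@dataclass
class SpatialTuningPattern:
    """Muscle x direction weight table plus per-muscle baseline activity."""

    weights: pd.DataFrame          # index: muscles, columns: direction labels
    baseline: pd.Series            # per-muscle fraction
    window_ms: float = 1000.0
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [d for d in self.weights.columns if d not in DIRECTIONS]
        if missing:
            raise StpError(f"unknown direction columns: {missing}")
        self.weights = self.weights[[d for d in DIRECTIONS if d in self.weights.columns]]
        self.baseline = self.baseline.reindex(self.weights.index)

    @property
    def muscles(self) -> list[str]:
        return list(self.weights.index)

    def restricted(self, muscles: Sequence[str]) -> "SpatialTuningPattern":
        return SpatialTuningPattern(self.weights.loc[list(muscles)].copy(),
                                    self.baseline.loc[list(muscles)].copy(),
                                    self.window_ms, self.provenance)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        table = self.weights.copy()
        table["baseline"] = self.baseline
        with open(path, "w") as fh:
            fh.write(f"# spatial tuning pattern; window_ms={self.window_ms}\n")
            if self.provenance:
                fh.write(f"# provenance: {self.provenance}\n")
            table.to_csv(fh, sep="\t", index_label="muscle",
                         float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpatialTuningPattern":
        window_ms, provenance = 1000.0, ""
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for ln in lines:
            if ln.startswith("#"):
                if "window_ms=" in ln:
                    window_ms = float(ln.split("window_ms=")[1].strip())
                elif "provenance:" in ln:
                    provenance = ln.split("provenance:", 1)[1].strip()
            else:
                body.append(ln)
        from io import StringIO
        table = pd.read_csv(StringIO("".join(body)), sep="\t", index_col="muscle")
        if "baseline" not in table.columns:
            raise StpError("STP table is missing the baseline column")
        baseline = table.pop("baseline")
        return cls(table, baseline, window_ms, provenance)


# ---------------------------------------------------------------------- ops

def normalize_emg(recording: EmgRecording, mvic: MvicTable) -> EmgRecording:
    """Divide the samples by the subject/muscle MVIC value."""
    value = mvic.get(recording.subject, recording.muscle)
    return EmgRecording(
        subject=recording.subject, muscle=recording.muscle,
        direction=recording.direction, samples=recording.samples / value,
        sample_rate=recording.sample_rate, loading_onset=recording.loading_onset,
    )


def extract_peak(recording: EmgRecording, window_ms: float = 1000.0) -> float:
    """Maximum normalized activity in [onset, onset + window]."""
    i0 = int(round(recording.loading_onset * recording.sample_rate))
    i1 = int(round((recording.loading_onset + window_ms / 1e3) * recording.sample_rate))
    if i1 > len(recording.samples):
        raise StpError(
            f"{recording.subject}/{recording.muscle}: peak window exceeds recording"
        )
    return float(np.max(recording.samples[i0:i1 + 1]))


def extract_baseline(recording: EmgRecording, pre_window_ms: float = 500.0) -> float:
    """Mean normalized activity over the window immediately before onset."""
    i1 = int(round(recording.loading_onset * recording.sample_rate))
    i0 = i1 - int(round(pre_window_ms / 1e3 * recording.sample_rate))
    if i0 < 0 or i1 <= i0:
        raise StpError(
            f"{recording.subject}/{recording.muscle}: pre-loading window does not fit"
        )
    return float(np.mean(recording.samples[i0:i1]))


def _biarticular_divisor(muscle: str, ratios: BiarticularRatios) -> float:
    if muscle.startswith("biceps"):
        return ratios.biceps_ratio
    if muscle.startswith("triceps"):
        return ratios.triceps_ratio
    return 1.0


def apply_biarticular_ratio(values, muscle: str,
                            ratios: BiarticularRatios | None = None):
    """Divide biceps/triceps values by their shoulder/elbow MVIC ratio;
    other muscles pass through unchanged."""
    ratios = ratios or BiarticularRatios()
    return np.asarray(values, dtype=float) / _biarticular_divisor(muscle, ratios)


def build_stp(recordings: Iterable[EmgRecording], mvic: MvicTable,
              ratios: BiarticularRatios | None = None,
              window_ms: float = 1000.0,
              pre_window_ms: float = 500.0,
              subjects: Sequence[str] | None = None) -> SpatialTuningPattern:
    """Construct an STP: per-subject windowed peaks, bi-articular rescaling,
    then averaging across subjects (peaks first, averaged table after).

    ``subjects`` optionally restricts the pool (e.g. one sex group); the
    default uses every subject present.
    """
    ratios = ratios or BiarticularRatios()
    peaks: dict[tuple[str, str], list[float]] = {}
    bases: dict[str, list[float]] = {}
    seen_muscles: list[str] = []
    for rec in recordings:
        if subjects is not None and rec.subject not in subjects:
            continue
        norm = normalize_emg(rec, mvic)
        div = _biarticular_divisor(rec.muscle, ratios)
        peaks.setdefault((rec.muscle, rec.direction), []).append(
            extract_peak(norm, window_ms) / div
        )
        bases.setdefault(rec.muscle, []).append(
            extract_baseline(norm, pre_window_ms) / div
        )
        if rec.muscle not in seen_muscles:
            seen_muscles.append(rec.muscle)
    if not peaks:
        raise StpError("no recordings supplied")
    for m in seen_muscles:
        for d in DIRECTIONS:
            if (m, d) not in peaks:
                raise StpError(f"no recordings for cell {m} x {d}")
    weights = pd.DataFrame(
        {d: [float(np.mean(peaks[(m, d)])) for m in seen_muscles] for d in DIRECTIONS},
        index=seen_muscles,
    )
    baseline = pd.Series({m: float(np.mean(bases[m])) for m in seen_muscles})
    return SpatialTuningPattern(weights, baseline, window_ms,
                                provenance="built from EMG recordings")


def rescale_for_controller(stp: SpatialTuningPattern,
                           included_muscles: Sequence[str]) -> SpatialTuningPattern:
    """Per-direction rescaling by the highest activity among the muscles
    included in the controller; each column maximum becomes exactly 1."""
    included = list(included_muscles)
    if not included:
        raise StpError("included_muscles must be non-empty")
    missing = [m for m in included if m not in stp.weights.index]
    if missing:
        raise StpError(f"muscles not in STP: {missing}")
    sub = stp.weights.loc[included].copy()
    maxima = sub.max(axis=0)
    bad = maxima[maxima <= 0]
    if len(bad):
        raise StpError(f"degenerate all-zero direction column(s): {list(bad.index)}")
    return SpatialTuningPattern(
        sub / maxima, stp.baseline.loc[included].copy(), stp.window_ms,
        provenance=(stp.provenance + "; rescaled for controller").strip("; "),
    )


# ------------------------------------------------------------------ file I/O

def read_emg_long(path: str | Path) -> list[EmgRecording]:
    """Read long-format EMG (columns: subject, muscle, direction, time_s,
    value; '#'-prefixed header lines carry sample_rate and loading_onset)."""
    meta = {"sample_rate": None, "loading_onset": None}
    with open(path) as fh:
        for ln in fh:
            if not ln.startswith("#"):
                break
            for key in meta:
                if f"{key}=" in ln:
                    meta[key] = float(ln.split(f"{key}=")[1].strip())
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"subject", "muscle", "direction", "time_s", "value"}
    if not required.issubset(df.columns):
        raise StpError(f"EMG file missing columns: {sorted(required - set(df.columns))}")
    recs = []
    for (subj, mus, d), grp in df.groupby(["subject", "muscle", "direction"], sort=False):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy()
        sr = meta["sample_rate"] or float(1.0 / np.median(np.diff(t)))
        onset = meta["loading_onset"] if meta["loading_onset"] is not None else 0.0
        recs.append(EmgRecording(str(subj), str(mus), str(d),
                                 grp["value"].to_numpy(), sr, onset))
    return recs


def write_emg_long(recordings: Sequence[EmgRecording], path: str | Path) -> None:
    r0 = recordings[0]
    rows = []
    for r in recordings:
        t = np.arange(len(r.samples)) / r.sample_rate
        rows.append(pd.DataFrame({
            "subject": r.subject, "muscle": r.muscle, "direction": r.direction,
            "time_s": t, "value": r.samples,
        }))
    with open(path, "w") as fh:
        fh.write(f"# sample_rate={r0.sample_rate}\n# loading_onset={r0.loading_onset}\n")
        pd.concat(rows, ignore_index=True).to_csv(fh, sep="\t", index=False,
                                                  float_format="%.8g")


def read_mvic(path: str | Path) -> MvicTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"subject", "muscle", "value"}
    if not required.issubset(df.columns):
        raise StpError(f"MVIC file missing columns: {sorted(required - set(df.columns))}")
    return MvicTable.from_frame(df)


def write_mvic(table: MvicTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")
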