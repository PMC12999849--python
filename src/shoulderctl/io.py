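"""Result serialization.

Trials are written as tab-separated tables with ``#`` metadata headers so
that runs can be archived, diffed, and re-read without the simulator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment import TrialResult


def write_trial(result: TrialResult, path: str | Path) -> None:
    """Write one trial as TSV: time, elbow XYZ, tension, theta, phi, and
    per-muscle activation columns; metadata in ``#`` header lines."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": result.time,
        "elbow_x_m": result.elbow[:, 0],
        "elbow_y_m": result.elbow[:, 1],
        "elbow_z_m": result.elbow[:, 2],
        "tension_N": result.tension,
        "theta_rad": result.theta,
        "phi_rad": result.phi,
    })
    for i, name in enumerate(result.muscle_names):
        df[f"act_{name}"] = result.activations[:, i]
    meta = {
        "direction": result.direction,
        "gain_label": result.gain_label,
        "reference_axis": [float(v) for v in result.reference_axis],
        "elbow0": [float(v) for v in result.elbow0],
        "dt": result.meta.get("dt"),
        "drop_mass": result.meta.get("drop_mass"),
    }
    with open(path, "w") as fh:
        fh.write(f"# trial: {json.dumps(meta)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_trial(path: str | Path) -> TrialResult:
    """Read a trial written by :func:`write_trial`."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# trial:"):
            meta = json.loads(first.split(":", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    act_cols = [c for c in df.columns if c.startswith("act_")]
    names = [c[len("act_"):] for c in act_cols]
    acts = df[act_cols].to_numpy() if act_cols else np.zeros((len(df), 0))
    return TrialResult(
        direction=meta.get("direction", ""),
        gain_label=meta.get("gain_label", ""),
        time=df["time_s"].to_numpy(),
        elbow=df[["elbow_x_m", "elbow_y_m", "elbow_z_m"]].to_numpy(),
        tension=df["tension_N"].to_numpy(),
        theta=df["theta_rad"].to_numpy(),
        phi=df["phi_rad"].to_numpy(),
        excitations=np.zeros((len(df), len(names))),
        activations=acts,
        muscle_names=names,
        reference_axis=np.asarray(meta.get("reference_axis", [1.0, 0.0, 0.0])),
        elbow0=np.asarray(meta.get("elbow0", [0.0, 0.0, 0.0])),
        meta={"dt": meta.get("dt"), "drop_mass": meta.get("drop_mass")},
    )


def summarize_trials(results: dict, window_ms: float = 800.0) -> pd.DataFrame:
    """Peak planar displacement and time-to-peak for a set of trials keyed
    by (gain label, direction) or by direction alone."""
    from .evaluation import peak_and_ttp, project_to_plane

    rows = []
    for key, res in results.items():
        label, direction = key if isinstance(key, tuple) else (res.gain_label, key)
        trace = project_to_plane(res.elbow, res.reference_axis, time=res.time)
        stats = peak_and_ttp([trace], "peak_of_average", window_ms=window_ms)
        rows.append({
            "gain_label": label,
            "direction": direction,
            "peak_mm": stats.peak,
            "ttp_s": stats.ttp,
            "theta_max_rad": res.peak_theta(),
            "tension_max_N": float(np.max(res.tension)),
        })
    return pd.DataFrame(rows)


def write_summary(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
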