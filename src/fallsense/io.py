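"""Reading and writing trial data.

Trials are exchanged as per-trial CSV sensor files plus a label manifest,
mirroring the layout of public fall datasets recorded with a 9-axis waist
sensor: a header row, a frame counter, and the six inertial channels (only
acceleration and gyroscope columns are consumed here).  Column names vary
between dataset dialects, so the reader takes a configurable column map;
accelerometer units can be declared as g or m/s^2 (the free-fall gate and
the attitude filter both assume g internally).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import GRAVITY_MS2, ImuTrial

__all__ = ["DEFAULT_COLUMNS", "write_trials_csv", "read_trials_csv"]

DEFAULT_COLUMNS = {
    "accel": ("AccX", "AccY", "AccZ"),
    "gyro": ("GyrX", "GyrY", "GyrZ"),
}

_MANIFEST = "manifest.csv"


def write_trials_csv(trials: list[ImuTrial], out_dir) -> Path:
    """Write one CSV per trial plus a manifest sheet; returns the manifest
    path.  Sensor files carry TimeStamp(s), FrameCounter and the six
    channels (accel in g, gyro in deg/s)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        fname = f"{trial.trial_id or trial.subject_id + '_' + trial.activity_code}.csv"
        t = np.arange(len(trial)) / trial.fs
        df = pd.DataFrame({
            "TimeStamp(s)": np.round(t, 4),
            "FrameCounter": np.arange(len(trial)),
            "AccX": trial.samples[:, 0], "AccY": trial.samples[:, 1],
            "AccZ": trial.samples[:, 2],
            "GyrX": trial.samples[:, 3], "GyrY": trial.samples[:, 4],
            "GyrZ": trial.samples[:, 5],
        })
        df.to_csv(out_dir / fname, index=False)
        rows.append({
            "file": fname, "trial_id": trial.trial_id,
            "subject_id": trial.subject_id, "activity_code": trial.activity_code,
            "is_fall": int(trial.is_fall),
            "onset_frame": trial.onset_frame if trial.onset_frame is not None else "",
            "impact_frame": trial.impact_frame if trial.impact_frame is not None else "",
            "fs": trial.fs,
        })
    manifest = out_dir / _MANIFEST
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_trials_csv(
    in_dir,
    manifest: str | Path | None = None,
    column_map: dict | None = None,
    accel_unit: str = "g",
) -> list[ImuTrial]:
    """Load trials from a directory of per-trial CSVs and a manifest.

    ``column_map`` overrides the default accel/gyro column names;
    ``accel_unit='m/s2'`` converts accelerations to g on read.
    """
    if accel_unit not in ("g", "m/s2"):
        raise ValueError("accel_unit must be 'g' or 'm/s2'")
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    in_dir = Path(in_dir)
    manifest = Path(manifest) if manifest else in_dir / _MANIFEST
    sheet = pd.read_csv(manifest)
    trials = []
    for _, row in sheet.iterrows():
        df = pd.read_csv(in_dir / row["file"])
        accel = df[list(cols["accel"])].to_numpy(dtype=float)
        gyro = df[list(cols["gyro"])].to_numpy(dtype=float)
        if accel_unit == "m/s2":
            accel = accel / GRAVITY_MS2
        def _frame(v):
            return None if pd.isna(v) or v == "" else int(v)
        trials.append(ImuTrial(
            subject_id=str(row["subject_id"]),
            activity_code=str(row["activity_code"]),
            is_fall=bool(int(row["is_fall"])),
            samples=np.column_stack([accel, gyro]),
            fs=float(row.get("fs", 100.0)),
            onset_frame=_frame(row.get("onset_frame")),
            impact_frame=_frame(row.get("impact_frame")),
            trial_id=str(row["trial_id"]),
        ))
    return trials
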