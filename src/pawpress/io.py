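"""Recording bundles and tabular output.

A recording bundle is a directory holding a human-inspectable pair:

* ``meta.json`` — platform and trial metadata (grid size, pitch,
  calibration, sampling rate, duration, subject/trial ids, optionally an
  ``active_mask_file`` pointing at a 0/1 CSV grid);
* ``frames.csv`` — the sparse frame table ``frame,row,col,pressure_kpa``
  (0-based indices, zeros omitted).

Writing followed by reading is the identity on frames and metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (PlatformSpec, PressureRecording, RecordingFormatError,
                   ValidationError)

__all__ = ["read_recording", "write_recording", "write_parameter_table"]

_META_KEYS = ("grid_rows", "grid_cols", "sensor_pitch_mm",
              "pressure_floor_kPa", "pressure_ceiling_kPa",
              "calibration_cap_kPa", "sampling_hz", "duration_s",
              "subject_id", "trial_id")


def write_recording(rec: PressureRecording, path) -> Path:
    """Write a recording bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spec = rec.spec
    meta = {
        "grid_rows": spec.grid_rows,
        "grid_cols": spec.grid_cols,
        "sensor_pitch_mm": spec.sensor_pitch_mm,
        "sensor_area_cm2": spec.sensor_area_cm2,
        "pressure_floor_kPa": spec.pressure_floor_kPa,
        "pressure_ceiling_kPa": spec.pressure_ceiling_kPa,
        "calibration_cap_kPa": spec.calibration_cap_kPa,
        "sampling_hz": spec.sampling_hz,
        "duration_s": rec.duration_s,
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
        "cap_applied": rec.cap_applied,
    }
    if spec.active_mask is not None:
        np.savetxt(path / "active_mask.csv", spec.active_mask.astype(int),
                   fmt="%d", delimiter=",")
        meta["active_mask_file"] = "active_mask.csv"
    (path / "meta.json").write_text(json.dumps(meta, indent=2))

    t, r, c = np.nonzero(rec.frames)
    df = pd.DataFrame({"frame": t, "row": r, "col": c,
                       "pressure_kpa": rec.frames[t, r, c]})
    # repr-precision floats so the round trip is bit exact
    df.to_csv(path / "frames.csv", index=False,
              float_format=lambda v: np.format_float_positional(v, trim="0"))
    return path


def read_recording(path) -> PressureRecording:
    """Read and validate a recording bundle written by :func:`write_recording`."""
    path = Path(path)
    meta_path = path / "meta.json"
    frames_path = path / "frames.csv"
    if not meta_path.exists() or not frames_path.exists():
        raise RecordingFormatError(f"{path} is not a recording bundle "
                                   "(need meta.json and frames.csv)")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as e:
        raise RecordingFormatError(f"malformed meta.json: {e}") from e
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise RecordingFormatError(f"meta.json missing keys: {missing}")

    mask = None
    if meta.get("active_mask_file"):
        mask = np.loadtxt(path / meta["active_mask_file"],
                          delimiter=",").astype(bool)
    spec = PlatformSpec(
        grid_rows=int(meta["grid_rows"]), grid_cols=int(meta["grid_cols"]),
        sensor_pitch_mm=float(meta["sensor_pitch_mm"]),
        sensor_area_cm2=float(meta.get("sensor_area_cm2", 1.0)),
        pressure_floor_kPa=float(meta["pressure_floor_kPa"]),
        pressure_ceiling_kPa=float(meta["pressure_ceiling_kPa"]),
        calibration_cap_kPa=float(meta["calibration_cap_kPa"]),
        sampling_hz=float(meta["sampling_hz"]),
        active_mask=mask,
    )
    duration = float(meta["duration_s"])
    n_frames = round(duration * spec.sampling_hz)

    df = pd.read_csv(frames_path, float_precision="round_trip")
    expected = {"frame", "row", "col", "pressure_kpa"}
    if set(df.columns) != expected:
        raise RecordingFormatError(
            f"frames.csv columns {list(df.columns)} != {sorted(expected)}")
    frames = np.zeros((n_frames, spec.grid_rows, spec.grid_cols))
    if len(df):
        t = df["frame"].to_numpy(dtype=int)
        r = df["row"].to_numpy(dtype=int)
        c = df["col"].to_numpy(dtype=int)
        if (t.min() < 0 or t.max() >= n_frames or r.min() < 0
                or r.max() >= spec.grid_rows or c.min() < 0
                or c.max() >= spec.grid_cols):
            raise ValidationError("frame/row/col index outside the declared "
                                  "grid or duration")
        p = df["pressure_kpa"].to_numpy(dtype=float)
        if np.any(p < 0):
            raise ValidationError("negative pressures in frames.csv")
        frames[t, r, c] = p
    return PressureRecording(spec, frames,
                             subject_id=str(meta["subject_id"]),
                             trial_id=str(meta["trial_id"]),
                             duration_s=duration,
                             cap_applied=bool(meta.get("cap_applied", False)))


def write_parameter_table(df: pd.DataFrame, path) -> Path:
    """Write a per-(subject, trial, limb) parameter table as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
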