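"""Standard-format I/O: array-container recordings, event TSVs, result
tables, and JSON metadata.

Recordings travel as ``.npz`` array containers (arrays: samples,
sampling_rate, start_time, channel_labels, optional airflow); events and
tabular results as TSV; configuration and run metadata as JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ContinuousRecording

__all__ = [
    "write_recording",
    "read_recording",
    "read_events",
    "write_events",
    "write_zmap_tsv",
    "write_json",
    "EVENT_COLUMNS",
    "CONDITIONS",
]

EVENT_COLUMNS = ["trial", "cue_time_s", "sniff_time_s", "condition", "correct"]
CONDITIONS = {"odor", "no_odor", "attended_no_odor"}


def write_recording(path, rec: ContinuousRecording) -> None:
    extra = {}
    airflow = getattr(rec, "airflow", None)
    if airflow is not None:
        extra["airflow"] = np.asarray(airflow)
    np.savez(path, samples=rec.samples, sampling_rate=rec.sampling_rate,
             start_time=rec.start_time,
             channel_labels=np.asarray(rec.channel_labels), **extra)


def read_recording(path) -> ContinuousRecording:
    with np.load(path, allow_pickle=False) as data:
        rec = ContinuousRecording(
            samples=data["samples"],
            sampling_rate=float(data["sampling_rate"]),
            channel_labels=[str(c) for c in data["channel_labels"]],
            start_time=float(data["start_time"]),
        )
        if "airflow" in data:
            rec.airflow = data["airflow"]
    return rec


def read_events(path) -> pd.DataFrame:
    """Read and validate an event table.

    TSV with header trial, cue_time_s, sniff_time_s, condition, correct.
    Conditions are case-normalized; unknown conditions raise.  Rows with
    cue after sniff are rejected with a warning; duplicate trial ids and
    non-monotone sniff times warn.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing column(s): {', '.join(missing)}")
    df = df[EVENT_COLUMNS].copy()
    df["condition"] = df["condition"].astype(str).str.strip().str.lower()
    unknown = set(df["condition"]) - CONDITIONS
    if unknown:
        raise ValueError(f"unknown condition(s): {sorted(unknown)} "
                         f"(expected one of {sorted(CONDITIONS)})")
    df["cue_time_s"] = df["cue_time_s"].astype(float)
    df["sniff_time_s"] = df["sniff_time_s"].astype(float)
    df["correct"] = df["correct"].astype(int)
    bad = df["cue_time_s"] > df["sniff_time_s"]
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} row(s) with cue_time_s > sniff_time_s")
        df = df[~bad].reset_index(drop=True)
    if df["trial"].duplicated().any():
        warnings.warn("duplicate trial ids in event table")
    if not df["sniff_time_s"].is_monotonic_increasing:
        warnings.warn("sniff times are not monotonically increasing")
    return df


def write_events(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_zmap_tsv(path, zmap) -> None:
    """Long-format z-map: band_hz, time_s, z, sig."""
    bands = np.repeat(zmap.band_centers, len(zmap.times))
    times = np.tile(zmap.times, len(zmap.band_centers))
    df = pd.DataFrame({
        "band_hz": bands,
        "time_s": times,
        "z": zmap.z.ravel(),
        "sig": zmap.significance_mask.ravel().astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
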