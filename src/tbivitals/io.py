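"""Readers and writers for waveforms, annotations, and tables.

Waveforms travel as two-column CSV (``time,value``; sampling rate inferred
from the median sample spacing) or as HDF5 with one dataset per channel and
``fs``/``channel``/``t0`` attributes. Cohort and feature tables are plain
CSV with a header row; feature tables get a sidecar schema file listing the
feature ids.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from tbivitals.types import BeatAnnotations, InputError, WaveformRecord

__all__ = [
    "write_waveform_csv",
    "read_waveform_csv",
    "write_waveform_hdf5",
    "read_waveform_hdf5",
    "write_annotations_csv",
    "write_feature_table",
    "read_feature_table",
]


def write_waveform_csv(record: WaveformRecord, path: str | Path) -> None:
    pd.DataFrame({"time": record.times, "value": record.samples}).to_csv(path, index=False)


def read_waveform_csv(path: str | Path, channel: str) -> WaveformRecord:
    df = pd.read_csv(path)
    if not {"time", "value"} <= set(df.columns):
        raise InputError(f"{path}: expected columns time,value")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise InputError(f"{path}: need at least 2 samples to infer the sampling rate")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise InputError(f"{path}: non-increasing time column")
    return WaveformRecord(df["value"].to_numpy(dtype=float), 1.0 / dt, channel, float(t[0]))


def write_waveform_hdf5(records: dict[str, WaveformRecord], path: str | Path) -> None:
    """Write named records (e.g. ``{"ecg": ..., "ppg": ...}``) to one file."""
    with h5py.File(path, "w") as f:
        for name, rec in records.items():
            ds = f.create_dataset(name, data=rec.samples)
            ds.attrs["fs"] = rec.fs
            ds.attrs["channel"] = rec.channel
            ds.attrs["t0"] = rec.t0


def read_waveform_hdf5(path: str | Path) -> dict[str, WaveformRecord]:
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            ds = f[name]
            out[name] = WaveformRecord(
                ds[()], float(ds.attrs["fs"]), str(ds.attrs["channel"]), float(ds.attrs.get("t0", 0.0))
            )
    return out


def write_annotations_csv(annotations: BeatAnnotations, path: str | Path) -> None:
    annotations.to_frame().to_csv(path, index=False)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-(patient, window) feature table plus a sidecar schema file."""
    path = Path(path)
    table.to_csv(path, index=False)
    schema = path.with_suffix(".schema.txt")
    schema.write_text("\n".join(table.columns) + "\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
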