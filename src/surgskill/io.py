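"""Readers and writers for the delimited on-disk formats.

EEG matrices are CSV with a channel-label header row and one column per
channel; EDF files are read through MNE when it is installed (read-only).
Gaze tables, attempt tables, feature tables, adjacency matrices and the
ground-truth ledger are plain delimited/JSON text.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import AdjacencyMatrix, AdjacencyStack
from .recordings import (EXCLUDED_CHANNELS, EegRecording, GazeRecording,
                         gaze_columns)


def write_eeg_csv(rec: EegRecording, path):
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format="%.6f")


def read_eeg_csv(path, fs_hz: float, exclude=EXCLUDED_CHANNELS,
                 **meta) -> EegRecording:
    df = pd.read_csv(path)
    keep = [c for c in df.columns if c not in set(exclude or ())]
    return EegRecording(keep, fs_hz, df[keep].to_numpy().T, **meta)


def read_eeg_edf(path, exclude=EXCLUDED_CHANNELS, **meta) -> EegRecording:
    """Read an EDF recording (requires the optional mne dependency)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("EDF reading requires the 'mne' package "
                          "(pip install surgskill[edf])") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    keep = [c for c in raw.ch_names if c not in set(exclude or ())]
    raw.pick(keep)
    return EegRecording(raw.ch_names, raw.info["sfreq"],
                        raw.get_data() * 1e6, **meta)  # volts -> microvolts


def read_eeg(path, fs_hz: float | None = None, **kw) -> EegRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_eeg_edf(path, **kw)
    if fs_hz is None:
        raise ValueError("fs_hz is required for delimited EEG files")
    return read_eeg_csv(path, fs_hz, **kw)


def write_gaze_csv(rec: GazeRecording, path):
    rec.samples.to_csv(path, index=False, float_format="%.6f")


def read_gaze_csv(path, fs_hz: float = 50.0, dominant_eye: str = "right",
                  **meta) -> GazeRecording:
    df = pd.read_csv(path)
    missing = set(gaze_columns()) - set(df.columns)
    if missing:
        raise ValueError(f"gaze file missing columns: {sorted(missing)}")
    return GazeRecording(df[gaze_columns()], fs_hz, dominant_eye, **meta)


def write_adjacency_csv(adj: AdjacencyMatrix, path):
    pd.DataFrame(adj.weights, index=adj.channel_labels,
                 columns=adj.channel_labels).to_csv(path)


def read_adjacency_csv(path, band) -> AdjacencyMatrix:
    df = pd.read_csv(path, index_col=0)
    return AdjacencyMatrix(df.to_numpy(), band, list(df.columns))


def write_adjacency_stack(stack: AdjacencyStack, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"band": stack.band.name, "window_s": stack.window_s,
                "windows": list(stack.window_indices)}
    for t, m in zip(stack.window_indices, stack):
        write_adjacency_csv(m, outdir / f"window_{t:04d}.csv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def write_feature_table(df: pd.DataFrame, path):
    df.reset_index().to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.set_index(["subject", "task", "attempt"])


def write_ledger(ledger: dict, path):
    """Ground-truth ledger as structured JSON text."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return {"index": [list(i) for i in o.index],
                    "columns": list(o.columns),
                    "data": o.to_numpy().tolist()}
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o).__name__)
    Path(path).write_text(json.dumps(ledger, default=default, indent=1))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
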