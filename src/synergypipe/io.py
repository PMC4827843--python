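"""Delimited-text readers/writers for recordings, matrices and reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import AccelTrace, EmgRecording


def write_emg(path: str | Path, recording: EmgRecording) -> None:
    recording.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_emg(path: str | Path, fs: float | None = None) -> EmgRecording:
    return EmgRecording.from_frame(pd.read_csv(path, sep="\t"), fs=fs)


def write_accel(path: str | Path, trace: AccelTrace) -> None:
    t = np.arange(trace.n_samples) / trace.fs
    pd.DataFrame({"time_s": t, "accel_g": trace.samples}).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_accel(path: str | Path, fs: float | None = None) -> AccelTrace:
    df = pd.read_csv(path, sep="\t")
    if "accel_g" not in df.columns:
        raise ValueError("expected an 'accel_g' column")
    if fs is None:
        t = df["time_s"].to_numpy(dtype=float)
        fs = 1.0 / float(np.median(np.diff(t)))
    return AccelTrace(df["accel_g"].to_numpy(dtype=float), fs)


def write_matrix(path: str | Path, m: np.ndarray, row_labels=None, col_labels=None) -> None:
    df = pd.DataFrame(m)
    if row_labels is not None:
        df.index = list(row_labels)
    if col_labels is not None:
        df.columns = list(col_labels)
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
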