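"""Reading and writing recordings, feature tables and comparison reports.

The proprietary acquisition export is not documented, so recordings travel
as plain comma-delimited text: a header ``time,ch01..ch12``, time in seconds,
one row per sample.  Feature tables and reports are long-format CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IngestError
from .model import N_CHANNELS, ArrayRecording, ChannelLayout

RECORDING_COLUMNS = ["time"] + [f"ch{i + 1:02d}" for i in range(N_CHANNELS)]
FEATURE_COLUMNS = ["subject_id", "group", "passage", "parameter", "value"]


def read_recording(
    path: str | Path,
    fs: float = 100.0,
    layout: ChannelLayout | None = None,
    meta: dict | None = None,
) -> ArrayRecording:
    """Read a delimited-text recording and validate it against ``fs``.

    The time column must be strictly increasing with mean spacing within 1%
    of ``1/fs``; any missing value is an ingest error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: not a parseable delimited file: {exc}") from exc
    if df.shape[1] != N_CHANNELS + 1:
        raise FormatError(
            f"{path}: expected a time column plus {N_CHANNELS} channels, "
            f"got {df.shape[1]} columns"
        )
    if df.isna().any().any():
        raise IngestError(f"{path}: missing values in recording")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    if abs(dt.mean() * fs - 1.0) > 0.01:
        raise FormatError(
            f"{path}: time spacing {dt.mean():.6g} s inconsistent with fs={fs} Hz"
        )
    samples = df.iloc[:, 1:].to_numpy(dtype=float)
    return ArrayRecording(
        samples,
        fs=fs,
        layout=layout or ChannelLayout.default(),
        meta=dict(meta or {}),
    )


def write_recording(recording: ArrayRecording, path: str | Path) -> None:
    """Write a recording as ``time,ch01..ch12`` CSV (lossless round trip)."""
    df = pd.DataFrame(
        np.column_stack([recording.times, recording.samples]),
        columns=RECORDING_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format feature table (one row per passage x parameter)."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise FormatError(f"feature table lacks columns {missing}")
    features.loc[:, FEATURE_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: feature table lacks columns {missing}")
    return df


def read_feature_dir(directory: str | Path) -> pd.DataFrame:
    """Concatenate every ``*.csv`` feature table in a directory (truth.csv excluded)."""
    directory = Path(directory)
    frames = [
        read_features(p)
        for p in sorted(directory.glob("*.csv"))
        if p.name != "truth.csv"
    ]
    if not frames:
        raise FormatError(f"{directory}: no feature tables found")
    return pd.concat(frames, ignore_index=True)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Comparison report, numbers rounded to 3 decimals in the printed style."""
    out = report.copy()
    for col in ("mean_a", "sd_a", "mean_b", "sd_b", "statistic", "p_value"):
        if col in out.columns:
            out[col] = out[col].round(3)
    out.to_csv(path, index=False)
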