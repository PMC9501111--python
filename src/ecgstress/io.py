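"""Plain-text I/O: ECG traces and stimulus event logs as CSV."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError


@dataclass
class ECGRecord:
    """A uniformly sampled single-lead voltage trace."""

    pid: str
    fs: float
    samples: np.ndarray
    event_log: Optional["EventLog"] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise FormatError("sampling rate must be > 0")
        if self.samples.size < 1:
            raise FormatError("record needs at least one sample")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class EventLog:
    """Ordered, non-overlapping labeled stimulus intervals (seconds)."""

    entries: List[Tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, label in self.entries:
            if start >= end:
                raise FormatError(f"event ({start}, {end}) has start >= end")
            if start < prev_end:
                raise FormatError(f"event starting at {start} overlaps the previous one")
            if label not in (0, 1):
                raise FormatError(f"label must be 0 or 1, got {label}")
            prev_end = end

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def read_ecg_csv(path, fs: Optional[float] = None, pid: Optional[str] = None) -> ECGRecord:
    """Read a two-column (time_s, amplitude_mV) CSV; header row optional.

    The sampling rate is inferred from the median spacing of the time column
    unless given explicitly.
    """
    path = Path(path)
    df = _read_numeric_csv(path, 2)
    t, x = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    if fs is None:
        if t.size < 2:
            raise FormatError(f"{path}: cannot infer rate from fewer than 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError(f"{path}: time column must be strictly increasing")
        fs = 1.0 / float(np.median(dt))
    return ECGRecord(pid=pid or path.stem, fs=fs, samples=x)


def write_ecg_csv(record: ECGRecord, path) -> None:
    t = np.arange(record.samples.size) / record.fs
    pd.DataFrame({"time_s": t, "ecg_mV": record.samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_event_log(path) -> EventLog:
    """Read a (start_s, end_s, label) CSV and validate ordering invariants."""
    df = _read_numeric_csv(Path(path), 3)
    entries = [
        (float(r.iloc[0]), float(r.iloc[1]), int(r.iloc[2])) for _, r in df.iterrows()
    ]
    return EventLog(entries=entries)


def write_event_log(log: EventLog, path) -> None:
    pd.DataFrame(log.entries, columns=["start_s", "end_s", "label"]).to_csv(path, index=False)


def _read_numeric_csv(path: Path, n_cols: int) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
        # header row optional: if the first row parsed as column names but is
        # numeric, re-read without a header
        if all(_is_number(c) for c in df.columns):
            df = pd.read_csv(path, header=None)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    if df.shape[1] < n_cols:
        raise FormatError(f"{path}: expected {n_cols} columns, found {df.shape[1]}")
    df = df.iloc[:, :n_cols]
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric values") from exc
    return df


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False
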