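"""Signal conditioning and window segmentation.

The denoising front end is a zero-phase (forward-backward) Butterworth
filter; the default is a 5th-order low-pass at a normalized cutoff of 0.3
(fraction of Nyquist). Zero-phase filtering is essential here: the features
downstream are wave *latencies*, which a causal filter would shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ParameterError
from .io import ECGRecord, EventLog

logger = logging.getLogger(__name__)


@dataclass
class LabeledWindow:
    """One fixed-length analysis window with its condition label."""

    pid: str
    start_s: float
    duration_s: float
    label: int
    fs: float
    samples: np.ndarray


def butterworth_filter(
    record: ECGRecord,
    order: int = 5,
    normalized_cutoff: float = 0.3,
    btype: str = "lowpass",
) -> ECGRecord:
    """Zero-phase Butterworth filter; cutoff is a fraction of Nyquist.

    Two passes square the magnitude response, so a component at normalized
    frequency f is attenuated by 1 / (1 + (f / Wn)^(2*order)).
    """
    if not 0.0 < normalized_cutoff < 1.0:
        raise ParameterError("normalized cutoff must lie strictly inside (0, 1)")
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    b, a = butter(order, normalized_cutoff, btype=btype)
    filtered = filtfilt(b, a, record.samples)
    return ECGRecord(pid=record.pid, fs=record.fs, samples=filtered, event_log=record.event_log)


def segment_windows(
    record: ECGRecord, log: EventLog, window_s: float = 10.0
) -> List[LabeledWindow]:
    """Cut one window per event, anchored at the event start.

    Events shorter than ``window_s`` (or running past the end of the
    recording) are skipped with a logged warning.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be > 0")
    n_win = int(round(window_s * record.fs))
    out: List[LabeledWindow] = []
    for start, end, label in log:
        if end - start < window_s:
            logger.warning(
                "skipping event (%.2f, %.2f): shorter than %.1f s window", start, end, window_s
            )
            continue
        i0 = int(round(start * record.fs))
        if i0 + n_win > record.samples.size:
            logger.warning(
                "skipping event (%.2f, %.2f): extends past end of recording", start, end
            )
            continue
        out.append(
            LabeledWindow(
                pid=record.pid,
                start_s=start,
                duration_s=window_s,
                label=int(label),
                fs=record.fs,
                samples=record.samples[i0 : i0 + n_win],
            )
        )
    return out
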