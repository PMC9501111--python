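"""QRS detection and P/Q/S/T wave delineation.

R peaks are found with a Pan-Tompkins-style pipeline (band-pass, derivative,
squaring, moving-window integration, adaptive threshold with a refractory
period). The four small waves are then located as signed extrema inside
physiology-based search windows around each R apex:

    Q : most negative sample in (R - 80 ms, R)
    S : most negative sample in (R, R + 80 ms)
    P : largest positive sample in (max(R - 300 ms, prev R + 410 ms), R - 80 ms)
    T : largest positive sample in (S + 80 ms, min(R + 450 ms, next R - 100 ms))

A wave is reported *missing* when its extremum does not stand out from the
local baseline by at least a configurable fraction of the beat's R amplitude.
Beats whose search windows would extend past the signal edge are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from .errors import DataError, ParameterError
from .params import WAVES
from .preprocess import LabeledWindow

SMALL_WAVES = ("P", "Q", "S", "T")


@dataclass
class SearchConfig:
    """Delineation search-window bounds (ms) and the missing-wave rule."""

    qs_halfwidth_ms: float = 80.0
    p_lookback_ms: float = 300.0
    t_lookahead_ms: float = 450.0
    t_start_after_s_ms: float = 80.0
    t_guard_before_next_r_ms: float = 100.0
    # P search never reaches into the previous beat's T region: start is
    # clamped to prev R + this clearance (latest typical T apex + 2 widths)
    p_guard_after_prev_r_ms: float = 410.0
    prominence_frac: float = 0.02  # of local R amplitude
    refractory_s: float = 0.2


@dataclass
class PeakSet:
    """Per-beat sample indices of the five waves; -1 marks a missing wave."""

    waves: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = {w: len(self.waves[w]) for w in WAVES}
        if len(set(n.values())) != 1:
            raise DataError(f"ragged per-wave index arrays: {n}")
        r = self.waves["R"]
        if np.any(r < 0):
            raise DataError("R must be present for every counted beat")
        for b in range(len(r)):
            present = [(w, self.waves[w][b]) for w in WAVES if self.waves[w][b] >= 0]
            idx = [i for _, i in present]
            if any(x >= y for x, y in zip(idx, idx[1:])):
                raise DataError(f"beat {b}: wave order violated: {present}")

    @property
    def n_beats(self) -> int:
        return len(self.waves["R"])

    def complete_beats(self, required: Iterable[str] = WAVES) -> int:
        req = list(required)
        if self.n_beats == 0:
            return 0
        mask = np.ones(self.n_beats, dtype=bool)
        for w in req:
            mask &= self.waves[w] >= 0
        return int(mask.sum())

    def indices(self, wave: str, present_only: bool = True) -> np.ndarray:
        idx = self.waves[wave]
        return idx[idx >= 0] if present_only else idx

    def to_frame(self, window_id: str, participant: str = "") -> pd.DataFrame:
        rows = []
        for b in range(self.n_beats):
            for w in WAVES:
                i = int(self.waves[w][b])
                rows.append((participant, window_id, b, w, max(i, -1), i >= 0))
        return pd.DataFrame(
            rows,
            columns=["participant", "window_id", "beat", "wave", "sample_index", "present"],
        )


def _signal_of(window: Union[LabeledWindow, np.ndarray]) -> np.ndarray:
    if isinstance(window, LabeledWindow):
        return window.samples
    return np.asarray(window, dtype=float)


def detect_r_peaks(
    window: Union[LabeledWindow, np.ndarray],
    fs: float,
    refractory_s: float = 0.2,
) -> np.ndarray:
    """Pan-Tompkins-style R detection; returns strictly increasing indices.

    Adaptive threshold = 0.5 x running mean of accepted integrated-peak
    heights (exponentially weighted), with a 200 ms refractory period.
    Returns an empty array when nothing crosses threshold.
    """
    x = _signal_of(window)
    if x.size < 2 * fs:
        raise DataError("need at least 2 s of signal for QRS detection")
    nyq = fs / 2.0
    lo, hi = 5.0 / nyq, min(15.0 / nyq, 0.99)
    b, a = butter(2, [lo, hi], btype="bandpass")
    band = filtfilt(b, a, x)
    deriv = np.gradient(band)
    sq = deriv * deriv
    win = max(int(round(0.150 * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    dist = max(int(round(refractory_s * fs)), 1)
    cand, _ = find_peaks(integ, distance=dist)
    if cand.size == 0:
        return np.array([], dtype=int)

    # adaptive acceptance in time order
    spki = float(np.max(integ[: int(2 * fs)]))
    if spki <= 0:
        return np.array([], dtype=int)
    accepted: List[int] = []
    for c in cand:
        h = integ[c]
        if h >= 0.5 * spki:
            accepted.append(int(c))
            spki = 0.125 * h + 0.875 * spki
    if not accepted:
        return np.array([], dtype=int)

    # refine to the raw-signal apex near each integrated peak
    half = int(round(0.10 * fs))
    refined: List[int] = []
    for c in accepted:
        lo_i, hi_i = max(c - half, 0), min(c + half + 1, x.size)
        refined.append(lo_i + int(np.argmax(x[lo_i:hi_i])))
    refined = sorted(set(refined))
    out: List[int] = []
    for r in refined:
        if not out or r - out[-1] >= dist:
            out.append(r)
        elif x[r] > x[out[-1]]:
            out[-1] = r
    return np.array(out, dtype=int)


def _extremum(
    seg: np.ndarray, offset: int, sign: int, floor: float
) -> int:
    """Signed extremum index within seg, or -1 if below the prominence floor.

    Prominence is measured as the extremum's signed excursion from the local
    (segment) median.
    """
    if seg.size == 0:
        return -1
    baseline = float(np.median(seg))
    vals = sign * (seg - baseline)
    i = int(np.argmax(vals))
    if vals[i] < floor:
        return -1
    return offset + i


def delineate_waves(
    window: Union[LabeledWindow, np.ndarray],
    fs: float,
    r_peaks: Sequence[int],
    config: Optional[SearchConfig] = None,
) -> PeakSet:
    """Locate P, Q, S, T per beat given R apices; see module docstring."""
    cfg = config or SearchConfig()
    x = _signal_of(window)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size == 0:
        raise DataError("delineation requires at least one R peak")

    def ms(v: float) -> int:
        return int(round(v * fs / 1000.0))

    qs_hw, p_lb, t_la = ms(cfg.qs_halfwidth_ms), ms(cfg.p_lookback_ms), ms(cfg.t_lookahead_ms)
    t_after_s, t_guard = ms(cfg.t_start_after_s_ms), ms(cfg.t_guard_before_next_r_ms)
    p_guard = ms(cfg.p_guard_after_prev_r_ms)

    out: Dict[str, List[int]] = {w: [] for w in WAVES}
    for k, r in enumerate(r_peaks):
        if r - p_lb < 0 or r + t_la >= x.size:
            continue  # search window would run past the signal edge: drop beat
        baseline = float(np.median(x[r - p_lb : r + t_la + 1]))
        r_amp = abs(x[r] - baseline)
        floor = cfg.prominence_frac * r_amp

        q = _extremum(x[r - qs_hw : r], r - qs_hw, -1, floor)
        s = _extremum(x[r + 1 : r + qs_hw + 1], r + 1, -1, floor)
        p_start = r - p_lb
        if k > 0:
            p_start = max(p_start, int(r_peaks[k - 1]) + p_guard)
        p = _extremum(x[p_start : r - qs_hw], p_start, +1, floor) if p_start < r - qs_hw else -1
        t_start = (s if s >= 0 else r) + t_after_s
        t_end = r + t_la
        if k + 1 < r_peaks.size:
            t_end = min(t_end, int(r_peaks[k + 1]) - t_guard)
        t = _extremum(x[t_start : t_end + 1], t_start, +1, floor) if t_end >= t_start else -1
        out["P"].append(p)
        out["Q"].append(q)
        out["R"].append(int(r))
        out["S"].append(s)
        out["T"].append(t)
    return PeakSet(waves={w: np.array(v, dtype=int) for w, v in out.items()})


def window_quality(
    peaks: PeakSet,
    required: Iterable[str] = WAVES,
    min_beats: int = 5,
) -> bool:
    """A window passes when at least ``min_beats`` beats have every required
    wave present — the reproducible stand-in for 'reliably detected'."""
    if min_beats < 1:
        raise ParameterError("min_beats must be >= 1")
    return peaks.complete_beats(required) >= min_beats
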