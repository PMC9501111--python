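"""Scoring automated delineation against reference annotations.

Detected and reference peak lists are matched one-to-one, nearest pair
first, inside a tolerance window (default +/-50 ms). Matched pairs are true
positives; leftover detections are false positives; leftover references are
false negatives. Study-level evaluation samples participants, pools counts
over their windows, and reports per-wave precision/recall/F1 distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DataError
from .params import WAVES


@dataclass
class MatchResult:
    """Per-wave-type matching counts and derived scores."""

    tp: int
    fp: int
    fn: int
    tolerance_ms: float
    zero_detections: bool = False

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def match_peaks(
    detected: Sequence[int],
    reference: Sequence[int],
    fs: float,
    tolerance_ms: float = 50.0,
) -> MatchResult:
    """Greedy nearest-first one-to-one matching within the tolerance window.

    Candidate pairs within tolerance are taken in order of increasing
    distance (ties broken by reference then detected position), each peak
    matched at most once.
    """
    det = np.asarray(detected, dtype=float)
    ref = np.asarray(reference, dtype=float)
    for name, arr in (("detected", det), ("reference", ref)):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise DataError(f"{name} peak list must be sorted")
    tol = tolerance_ms * fs / 1000.0

    pairs = []
    for i, r in enumerate(ref):
        lo = np.searchsorted(det, r - tol, side="left")
        hi = np.searchsorted(det, r + tol, side="right")
        for j in range(lo, hi):
            pairs.append((abs(det[j] - r), i, j))
    pairs.sort()
    ref_used = np.zeros(ref.size, dtype=bool)
    det_used = np.zeros(det.size, dtype=bool)
    tp = 0
    for _, i, j in pairs:
        if not ref_used[i] and not det_used[j]:
            ref_used[i] = det_used[j] = True
            tp += 1
    return MatchResult(
        tp=tp,
        fp=int(det.size - tp),
        fn=int(ref.size - tp),
        tolerance_ms=tolerance_ms,
        zero_detections=det.size == 0,
    )


def _wave_indices(frame: pd.DataFrame, wave: str) -> np.ndarray:
    sub = frame[(frame["wave"] == wave) & frame["present"]]
    return np.sort(sub["sample_index"].to_numpy())


def evaluate_study(
    detections: pd.DataFrame,
    ground_truth: pd.DataFrame,
    fs: float,
    n_participants_sample: int = 10,
    seed: int = 0,
    tolerance_ms: float = 50.0,
    valid_range: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Per-participant, per-wave precision/recall/F1 on a participant sample.

    Both inputs use the shared peak-set schema (participant, window_id, beat,
    wave, sample_index, present). ``valid_range`` (lo, hi), in samples within
    a window, restricts scoring to the region where the delineator is defined
    (it drops beats whose search windows cross the window edges): whole beats
    whose R apex lies outside the range are excluded from both the detected
    and the reference peaks.
    """
    participants = sorted(ground_truth["participant"].unique())
    rng = np.random.default_rng(seed)
    if n_participants_sample < len(participants):
        sample = sorted(rng.choice(participants, n_participants_sample, replace=False))
    else:
        sample = participants

    def clip(frame: pd.DataFrame) -> pd.DataFrame:
        if valid_range is None or frame.empty:
            return frame
        lo, hi = valid_range
        r = frame[(frame["wave"] == "R") & frame["present"]]
        ok = r[(r["sample_index"] >= lo) & (r["sample_index"] < hi)]
        keys = set(zip(ok["window_id"], ok["beat"]))
        mask = [
            (w, b) in keys for w, b in zip(frame["window_id"], frame["beat"])
        ]
        return frame[mask]

    rows = []
    for pid in sample:
        det_p = clip(detections[detections["participant"] == pid])
        ref_p = clip(ground_truth[ground_truth["participant"] == pid])
        windows = sorted(ref_p["window_id"].unique())
        for wave in WAVES:
            tp = fp = fn = 0
            for wid in windows:
                det_w = _wave_indices(det_p[det_p["window_id"] == wid], wave)
                ref_w = _wave_indices(ref_p[ref_p["window_id"] == wid], wave)
                m = match_peaks(det_w, ref_w, fs, tolerance_ms)
                tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
            res = MatchResult(tp=tp, fp=fp, fn=fn, tolerance_ms=tolerance_ms)
            rows.append((pid, wave, res.precision, res.recall, res.f1, tp, fp, fn))
    return pd.DataFrame(
        rows, columns=["participant", "wave", "precision", "recall", "f1", "tp", "fp", "fn"]
    )


def summarize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of each score per wave, over participants."""
    out = []
    for wave in WAVES:
        sub = scores[scores["wave"] == wave]
        row = {"wave": wave}
        for m in ("precision", "recall", "f1"):
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)
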