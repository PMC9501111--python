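"""Time-domain HRV features and small-peak interval features.

Two feature families are computed per 10 s window:

* 24 *traditional* features, all derived from the R-R (NN) interval series —
  the standard time-domain HRV canon (MeanNN, SDNN, RMSSD, pNNxx, geometric
  measures TINN/HTI, distribution shape, ...).
* 12 *novel* small-peak features: the mean and sample standard deviation of
  the six within-beat peak-to-peak intervals PR, PS, PT, QS, QT and ST.

Units: all interval features in ms, pNN features in percent, coefficients of
variation / HTI / shape measures dimensionless. Sample (n-1) standard
deviations are used throughout.

Two deliberate departures from loose textual definitions seen in the
literature: MedianNN is the median of the RR intervals themselves (not of
successive differences), and pNNxx counts successive differences strictly
greater than the threshold.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .delineate import PeakSet
from .errors import DataError, ParameterError

#: histogram bin width (ms) for TINN and HTI; the 1/128 s convention
DEFAULT_BIN_WIDTH_MS = 7.8125

TRADITIONAL_FEATURES: Tuple[str, ...] = (
    "MeanNN", "SDNN", "RMSSD", "SDSD", "CVNN", "CVSD",
    "MedianNN", "MadNN", "MCVNN", "IQRNN", "Prc20NN", "Prc80NN",
    "MinNN", "MaxNN", "RangeNN", "pNN50", "pNN20", "pNN10",
    "TINN", "HTI", "SDRMSSD", "SkewNN", "KurtNN", "MeanAbsDiff",
)

INTERVAL_WAVES: Dict[str, Tuple[str, str]] = {
    "PR": ("P", "R"), "PS": ("P", "S"), "PT": ("P", "T"),
    "QS": ("Q", "S"), "QT": ("Q", "T"), "ST": ("S", "T"),
}

NOVEL_FEATURES: Tuple[str, ...] = tuple(
    f"{iv}_{stat}" for iv in INTERVAL_WAVES for stat in ("mean", "sd")
)

ALL_FEATURES: Tuple[str, ...] = TRADITIONAL_FEATURES + NOVEL_FEATURES

META_COLUMNS = ("pid", "window_id", "stress")


def rr_from_peaks(r_peaks: Sequence[int], fs: float) -> np.ndarray:
    """Successive R-R intervals in ms from strictly increasing peak indices."""
    r = np.asarray(r_peaks)
    if r.size < 2:
        raise DataError("need at least 2 R peaks for an RR series")
    d = np.diff(r)
    if np.any(d <= 0):
        raise DataError("R peak indices must be strictly increasing")
    return d.astype(float) * 1000.0 / fs


def _rr_histogram(rr: np.ndarray, bin_width_ms: float) -> Tuple[np.ndarray, np.ndarray]:
    lo = math.floor(rr.min() / bin_width_ms) * bin_width_ms
    hi = math.ceil(rr.max() / bin_width_ms) * bin_width_ms
    if hi <= lo:
        hi = lo + bin_width_ms
    edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
    counts, _ = np.histogram(rr, bins=edges)
    return counts.astype(float), edges


def triangular_fit_tinn(rr: np.ndarray, bin_width_ms: float = DEFAULT_BIN_WIDTH_MS) -> float:
    """TINN: base width (ms) of the least-squares triangular fit to the RR
    histogram, apex pinned at the modal bin.

    All (N, M) pairs of bin edges flanking the mode are searched exhaustively;
    the triangle is zero outside [N, M] and linear to the apex.
    """
    counts, edges = _rr_histogram(rr, bin_width_ms)
    centers = (edges[:-1] + edges[1:]) / 2.0
    m = int(np.argmax(counts))
    x_apex, y_apex = centers[m], counts[m]
    n_candidates = edges[: m + 1]
    m_candidates = edges[m + 1 :]
    best = (np.inf, bin_width_ms)
    for n_edge in n_candidates:
        for m_edge in m_candidates:
            q = np.zeros_like(counts)
            left = (centers > n_edge) & (centers <= x_apex)
            right = (centers > x_apex) & (centers < m_edge)
            if x_apex > n_edge:
                q[left] = y_apex * (centers[left] - n_edge) / (x_apex - n_edge)
            if m_edge > x_apex:
                q[right] = y_apex * (m_edge - centers[right]) / (m_edge - x_apex)
            sse = float(np.sum((counts - q) ** 2))
            width = m_edge - n_edge
            if sse < best[0] - 1e-12 or (abs(sse - best[0]) <= 1e-12 and width < best[1]):
                best = (sse, width)
    return float(best[1])


def hrv_triangular_index(rr: np.ndarray, bin_width_ms: float = DEFAULT_BIN_WIDTH_MS) -> float:
    """HTI: total RR count divided by the modal histogram bin count."""
    counts, _ = _rr_histogram(rr, bin_width_ms)
    return float(rr.size / counts.max())


def hrv_time_features(
    rr: Sequence[float], bin_width_ms: float = DEFAULT_BIN_WIDTH_MS
) -> Dict[str, float]:
    """The 24 traditional R-peak HRV features for one window."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise DataError("successive-difference features need >= 2 RR intervals")
    if np.any(rr <= 0):
        raise DataError("RR intervals must be positive")
    d = np.diff(rr)
    abs_d = np.abs(d)
    mean_nn = float(rr.mean())
    sdnn = float(rr.std(ddof=1))
    rmssd = float(np.sqrt(np.mean(d * d)))
    median_nn = float(np.median(rr))
    mad_nn = float(1.4826 * np.median(np.abs(rr - median_nn)))
    q1, q3 = np.percentile(rr, [25, 75])
    if sdnn > 0:
        skew = float(stats.skew(rr))
        kurt = float(stats.kurtosis(rr))
    else:
        skew = kurt = 0.0
    return {
        "MeanNN": mean_nn,
        "SDNN": sdnn,
        "RMSSD": rmssd,
        "SDSD": float(d.std(ddof=1)) if d.size >= 2 else 0.0,
        "CVNN": sdnn / mean_nn,
        "CVSD": rmssd / mean_nn,
        "MedianNN": median_nn,
        "MadNN": mad_nn,
        "MCVNN": mad_nn / median_nn,
        "IQRNN": float(q3 - q1),
        "Prc20NN": float(np.percentile(rr, 20)),
        "Prc80NN": float(np.percentile(rr, 80)),
        "MinNN": float(rr.min()),
        "MaxNN": float(rr.max()),
        "RangeNN": float(rr.max() - rr.min()),
        "pNN50": float(100.0 * np.count_nonzero(abs_d > 50.0) / d.size),
        "pNN20": float(100.0 * np.count_nonzero(abs_d > 20.0) / d.size),
        "pNN10": float(100.0 * np.count_nonzero(abs_d > 10.0) / d.size),
        "TINN": triangular_fit_tinn(rr, bin_width_ms),
        "HTI": hrv_triangular_index(rr, bin_width_ms),
        "SDRMSSD": sdnn / rmssd if rmssd > 0 else 0.0,
        "SkewNN": skew,
        "KurtNN": kurt,
        "MeanAbsDiff": float(abs_d.mean()),
    }


def small_peak_features(
    peaks: PeakSet, fs: float, min_beats: int = 3
) -> Dict[str, float]:
    """The 12 novel features: mean and sd (ms) of each within-beat interval.

    An interval is measured only on beats where both of its waves are
    present; with fewer than ``min_beats`` usable beats the feature pair is
    NaN (the window then fails quality filtering upstream).
    """
    out: Dict[str, float] = {}
    for name, (wa, wb) in INTERVAL_WAVES.items():
        ia, ib = peaks.waves[wa], peaks.waves[wb]
        ok = (ia >= 0) & (ib >= 0)
        vals = (ib[ok] - ia[ok]).astype(float) * 1000.0 / fs
        if vals.size < min_beats:
            out[f"{name}_mean"] = float("nan")
            out[f"{name}_sd"] = float("nan")
        else:
            out[f"{name}_mean"] = float(vals.mean())
            out[f"{name}_sd"] = float(vals.std(ddof=1))
    return out


def window_features(
    rr: Sequence[float], peaks: PeakSet, fs: float,
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS,
) -> Dict[str, float]:
    """All 36 candidate features for one window."""
    feats = hrv_time_features(rr, bin_width_ms)
    feats.update(small_peak_features(peaks, fs))
    return feats


def zscore_table(
    table: pd.DataFrame, columns: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Z-score each feature column over the full table (pooled across
    participants and conditions), using the sample sd.

    Metadata columns (pid, window_id, stress) are passed through untouched.
    Idempotent to numerical precision. Raises on a constant column.
    """
    if len(table) < 2:
        raise DataError("z-scoring needs at least 2 rows")
    if columns is None:
        columns = [c for c in table.columns if c not in META_COLUMNS]
    out = table.copy()
    for c in columns:
        col = table[c].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ParameterError(f"cannot z-score constant or non-finite column {c!r}")
        out[c] = (col - col.mean()) / sd
    out.attrs["scaled"] = True
    return out
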