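"""Shared test utilities: independent oracles and ground-truth adapters."""

from __future__ import annotations

import math
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from ecgstress import PeakSet
from ecgstress.simulate import GroundTruth, StudyBundle


def peaks_from_truth(gt: GroundTruth) -> PeakSet:
    """Treat the generator's planted wave indices as a delineation result."""
    return PeakSet(waves={w: gt.wave_indices[w].copy() for w in gt.wave_indices})


def feature_table_from_truth(bundle: StudyBundle) -> pd.DataFrame:
    """Feature table computed from planted annotations (no signal needed)."""
    from ecgstress import window_features

    rows = []
    for pid, wid, gt in bundle.iter_windows():
        r = gt.wave_indices["R"]
        rr = np.diff(r[r >= 0]).astype(float) * 1000.0 / gt.fs
        feats = window_features(rr, peaks_from_truth(gt), gt.fs)
        feats.update({"pid": pid, "window_id": wid, "stress": gt.label})
        rows.append(feats)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# first-principles HRV oracle: pure Python, no numpy, defined independently
# ---------------------------------------------------------------------------

def _quantile(sorted_vals: List[float], q: float) -> float:
    """Linear-interpolation quantile on pre-sorted data."""
    n = len(sorted_vals)
    pos = q * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def hrv_oracle(rr: Sequence[float]) -> Dict[str, float]:
    rr = [float(v) for v in rr]
    n = len(rr)
    mean = sum(rr) / n
    var = sum((v - mean) ** 2 for v in rr) / (n - 1)
    d = [b - a for a, b in zip(rr, rr[1:])]
    rmssd = math.sqrt(sum(x * x for x in d) / len(d))
    s = sorted(rr)
    return {
        "MeanNN": mean,
        "SDNN": math.sqrt(var),
        "RMSSD": rmssd,
        "MedianNN": _quantile(s, 0.5),
        "IQRNN": _quantile(s, 0.75) - _quantile(s, 0.25),
        "pNN50": 100.0 * sum(1 for x in d if abs(x) > 50.0) / len(d),
        "pNN20": 100.0 * sum(1 for x in d if abs(x) > 20.0) / len(d),
    }


def brute_force_max_matching(detected: Sequence[float], reference: Sequence[float], tol: float) -> int:
    """Maximum one-to-one matching cardinality by exhaustive recursion."""

    def rec(i: int, used: frozenset) -> int:
        if i == len(reference):
            return 0
        best = rec(i + 1, used)  # leave reference[i] unmatched
        for j, dv in enumerate(detected):
            if j not in used and abs(dv - reference[i]) <= tol:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())
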