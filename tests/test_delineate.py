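import dataclasses

import numpy as np
import pytest

import ecgstress as es
from ecgstress.delineate import PeakSet
from ecgstress.errors import DataError
from ecgstress.evaluate import evaluate_study, summarize_scores
from conftest import delineate_study, study_margin


def _filtered(sig, fs):
    rec = es.ECGRecord(pid="t", fs=fs, samples=sig)
    return es.butterworth_filter(rec).samples


class TestDetectRPeaks:
    def test_clean_constant_rr_count_and_accuracy(self):
        fs = 1000.0
        cond = dataclasses.replace(es.rest_condition(), mean_rr_ms=1000.0, sd_rr_ms=0.0)
        rr = np.full(11, 1000.0)
        sig, gt = es.synthesize_window(
            rr, es.MorphologyParams(), cond, es.zero_noise(), fs, 0
        )
        sig = sig[: 10_000]  # 10 s
        r = es.detect_r_peaks(sig, fs)
        true_r = gt.wave_indices["R"][gt.wave_indices["R"] < 10_000]
        assert abs(len(r) - 10) <= 1
        for d in r:
            assert np.min(np.abs(true_r - d)) <= 10  # +/-10 ms at 1000 Hz

    def test_all_zero_signal_gives_empty_list(self):
        assert es.detect_r_peaks(np.zeros(5000), 1000.0).size == 0

    def test_fast_rate_count(self):
        fs = 1000.0
        cond = dataclasses.replace(
            es.rest_condition(),
            mean_rr_ms=600.0,
            sd_rr_ms=0.0,
            # shorten the beat so waves fit into the 600 ms cycle
            interval_means_ms={"PR": 140.0, "QR": 40.0, "RS": 40.0, "ST": 200.0},
        )
        rr = np.full(18, 600.0)
        sig, _ = es.synthesize_window(rr, es.MorphologyParams(), cond, es.zero_noise(), fs, 0)
        r = es.detect_r_peaks(sig[:10_000], fs)
        assert 16 <= len(r) <= 17

    def test_refractory_period_enforced(self, noisy_study):
        part = noisy_study.participants[0]
        fs = noisy_study.layout.fs
        r = es.detect_r_peaks(part.signal[: int(10 * fs)], fs)
        assert np.all(np.diff(r) >= int(0.2 * fs))


class TestDelineateWaves:
    def test_zero_noise_recovers_planted_waves_exactly(self, clean_window):
        sig, gt = clean_window
        fs = 1000.0
        x = _filtered(sig, fs)
        r = es.detect_r_peaks(x, fs)
        ps = es.delineate_waves(x, fs, r)
        assert ps.n_beats > 0
        for w in ("P", "Q", "R", "S", "T"):
            det = ps.indices(w)
            true = gt.wave_indices[w]
            for d in det:
                assert np.min(np.abs(true[true >= 0] - d)) <= 1

    def test_random_morphologies_full_recall(self):
        # delineation recovers every planted wave at +/-20 ms on zero noise
        fs, tol = 500.0, 20e-3 * 500.0
        rng = np.random.default_rng(123)
        n_ok = 0
        for trial in range(50):
            amps = {
                "P": rng.uniform(0.1, 0.3),
                "Q": -rng.uniform(0.05, 0.2),
                "R": 1.0,
                "S": -rng.uniform(0.1, 0.4),
                "T": rng.uniform(0.2, 0.5),
            }
            widths = {
                "P": rng.uniform(18, 28), "Q": rng.uniform(8, 14), "R": rng.uniform(7, 10),
                "S": rng.uniform(8, 14), "T": rng.uniform(30, 42),
            }
            morph = es.MorphologyParams(
                amplitudes=amps,
                offsets_ms={"P": -160.0, "Q": -40.0, "R": 0.0, "S": 40.0, "T": 300.0},
                widths_ms=widths,
            )
            cond = es.rest_condition()
            rr = es.generate_rr_series(cond, 10, int(rng.integers(1 << 30)))
            sig, gt = es.synthesize_window(
                rr, morph, cond, es.zero_noise(), fs, int(rng.integers(1 << 30))
            )
            x = _filtered(sig, fs)
            r = es.detect_r_peaks(x, fs)
            ps = es.delineate_waves(x, fs, r)
            # evaluate only beats the delineator is defined on: R far enough
            # from both signal edges for the full search window
            cfg = es.SearchConfig()
            p_lb = int(round(cfg.p_lookback_ms * fs / 1000.0))
            t_la = int(round(cfg.t_lookahead_ms * fs / 1000.0))
            r_true = gt.wave_indices["R"]
            recall_ok = True
            for b in np.flatnonzero((r_true >= p_lb) & (r_true + t_la < sig.size)):
                for w in ("P", "Q", "R", "S", "T"):
                    t = gt.wave_indices[w][b]
                    det = ps.indices(w)
                    if t < 0:
                        continue
                    if det.size == 0 or np.min(np.abs(det - t)) > tol:
                        recall_ok = False
            n_ok += recall_ok
        assert n_ok == 50

    def test_absent_q_marked_missing(self):
        fs = 1000.0
        morph = es.MorphologyParams(
            amplitudes={"P": 0.22, "Q": 0.0, "R": 1.0, "S": -0.25, "T": 0.35}
        )
        cond = es.rest_condition()
        rr = es.generate_rr_series(cond, 10, 3)
        sig, _ = es.synthesize_window(rr, morph, cond, es.zero_noise(), fs, 4)
        x = _filtered(sig, fs)
        r = es.detect_r_peaks(x, fs)
        ps = es.delineate_waves(x, fs, r)
        assert np.all(ps.waves["Q"] == -1)
        assert np.all(ps.waves["S"] >= 0)

    def test_empty_r_list_rejected(self):
        with pytest.raises(DataError):
            es.delineate_waves(np.zeros(5000), 1000.0, [])

    def test_ordering_invariant_enforced_by_peakset(self):
        with pytest.raises(DataError):
            PeakSet(
                waves={
                    "P": np.array([100]), "Q": np.array([90]), "R": np.array([80]),
                    "S": np.array([120]), "T": np.array([200]),
                }
            )

    def test_noise_degrades_f1_monotonically(self):
        # per-wave F1 never increases with white-noise sd (0.02 slack), on a
        # fixed default morphology so every wave starts above the prominence
        # floor and the sweep isolates the effect of noise alone
        fs = 500.0
        cond = es.rest_condition()
        morph = es.MorphologyParams()
        f1_by_level = []
        for sd in (0.0, 0.03, 0.08, 0.15):
            noise = dataclasses.replace(es.zero_noise(), white_sd_mv=sd)
            counts = {w: [0, 0, 0] for w in ("P", "Q", "R", "S", "T")}  # tp, fp, fn
            for k in range(20):
                rr = es.generate_rr_series(cond, 14, 1000 + k)
                sig, gt = es.synthesize_window(rr, morph, cond, noise, fs, 2000 + k)
                x = _filtered(sig, fs)
                r = es.detect_r_peaks(x, fs)
                if r.size == 0:
                    continue
                ps = es.delineate_waves(x, fs, r)
                lo, hi = int(0.3 * fs), sig.size - int(0.45 * fs)
                for w in counts:
                    det = ps.indices(w)
                    det = det[(det >= lo) & (det < hi)]
                    true = gt.wave_indices[w]
                    true = np.sort(true[(true >= lo) & (true < hi)])
                    m = es.match_peaks(np.sort(det), true, fs, tolerance_ms=20.0)
                    counts[w][0] += m.tp
                    counts[w][1] += m.fp
                    counts[w][2] += m.fn
            f1 = {}
            for w, (tp, fp, fn) in counts.items():
                p = tp / (tp + fp) if tp + fp else 0.0
                rcl = tp / (tp + fn) if tp + fn else 0.0
                f1[w] = 2 * p * rcl / (p + rcl) if p + rcl else 0.0
            f1_by_level.append(f1)
        for lo_lvl, hi_lvl in zip(f1_by_level, f1_by_level[1:]):
            for w in lo_lvl:
                assert hi_lvl[w] <= lo_lvl[w] + 0.02, (w, f1_by_level)


class TestWindowQuality:
    def _peakset(self, n_complete, n_partial):
        waves = {w: [] for w in ("P", "Q", "R", "S", "T")}
        base = 400
        for b in range(n_complete + n_partial):
            r = base + b * 800
            waves["P"].append(r - 160)
            waves["Q"].append(r - 40 if b < n_complete else -1)
            waves["R"].append(r)
            waves["S"].append(r + 40)
            waves["T"].append(r + 300)
        return PeakSet(waves={w: np.array(v) for w, v in waves.items()})

    def test_all_complete_passes(self):
        assert es.window_quality(self._peakset(8, 0), min_beats=5)

    def test_zero_beats_fails(self):
        empty = PeakSet(waves={w: np.array([], dtype=int) for w in ("P", "Q", "R", "S", "T")})
        assert not es.window_quality(empty, min_beats=5)

    def test_threshold_boundary(self):
        assert not es.window_quality(self._peakset(4, 6), min_beats=5)
        assert es.window_quality(self._peakset(5, 5), min_beats=5)
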