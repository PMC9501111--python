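"""Parameter containers for the synthetic ECG study generator.

The generator plants a five-wave (P, Q, R, S, T) Gaussian beat template on an
AR(1) RR-interval process. Wave positions within a beat are controlled by four
*primitive* peak-to-peak intervals, all in milliseconds and all measured
between wave apices:

    PR : P to R (P sits at -PR relative to R)
    QR : Q to R (Q sits at -QR)
    RS : R to S (S sits at +RS)
    ST : S to T (T sits at +RS+ST)

Every other pairwise interval is a sum of primitives (e.g. PT = PR + RS + ST),
so the six intervals the feature extractor measures are fully determined while
each primitive carries its own independent beat-to-beat jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping

from .errors import MorphologyError, ParameterError

WAVES = ("P", "Q", "R", "S", "T")

#: primitive peak-to-peak intervals; see module docstring
PRIMITIVE_INTERVALS = ("PR", "QR", "RS", "ST")


@dataclass(frozen=True)
class MorphologyParams:
    """Per-wave Gaussian beat template: amplitude (mV), apex offset from R (ms),
    width (ms, Gaussian standard deviation).

    Offsets define the *rest-state template*; at synthesis time the actual
    per-beat wave placement comes from :class:`ConditionParams` intervals.
    """

    amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"P": 0.22, "Q": -0.08, "R": 1.0, "S": -0.25, "T": 0.35}
    )
    offsets_ms: Mapping[str, float] = field(
        default_factory=lambda: {"P": -160.0, "Q": -40.0, "R": 0.0, "S": 40.0, "T": 300.0}
    )
    widths_ms: Mapping[str, float] = field(
        default_factory=lambda: {"P": 22.0, "Q": 10.0, "R": 8.0, "S": 10.0, "T": 36.0}
    )

    def __post_init__(self) -> None:
        for coll in (self.amplitudes, self.offsets_ms, self.widths_ms):
            missing = set(WAVES) - set(coll)
            if missing:
                raise MorphologyError(f"missing wave entries: {sorted(missing)}")
        r_amp = abs(self.amplitudes["R"])
        for w in WAVES:
            if w != "R" and abs(self.amplitudes[w]) >= r_amp:
                raise MorphologyError(f"|R| amplitude must dominate; {w} violates this")
        off = [self.offsets_ms[w] for w in WAVES]
        if self.offsets_ms["R"] != 0.0:
            raise MorphologyError("R offset must be 0 (R anchors the beat)")
        if not all(a < b for a, b in zip(off, off[1:])):
            raise MorphologyError("wave offsets must be strictly ordered P < Q < R < S < T")
        for w in WAVES:
            if self.widths_ms[w] <= 0:
                raise MorphologyError(f"width of {w} must be > 0")
        # adjacent apices closer than the sum of their widths smear into one extremum
        for a, b in zip(WAVES, WAVES[1:]):
            gap = self.offsets_ms[b] - self.offsets_ms[a]
            if gap < self.widths_ms[a] + self.widths_ms[b]:
                raise MorphologyError(
                    f"waves {a} and {b} overlap: gap {gap:.1f} ms < "
                    f"{self.widths_ms[a] + self.widths_ms[b]:.1f} ms"
                )

    def rest_intervals(self) -> Dict[str, float]:
        """Primitive intervals implied by the template offsets."""
        return {
            "PR": -self.offsets_ms["P"],
            "QR": -self.offsets_ms["Q"],
            "RS": self.offsets_ms["S"],
            "ST": self.offsets_ms["T"] - self.offsets_ms["S"],
        }


@dataclass(frozen=True)
class ConditionParams:
    """RR process and within-beat interval statistics for one condition.

    mean_rr_ms / sd_rr_ms / rr_autocorr parameterise the truncated AR(1)
    RR-interval process; interval_means_ms / interval_sds_ms give the mean and
    independent beat-to-beat jitter sd of each primitive interval.
    """

    mean_rr_ms: float = 850.0
    sd_rr_ms: float = 50.0
    rr_autocorr: float = 0.3
    interval_means_ms: Mapping[str, float] = field(
        default_factory=lambda: {"PR": 160.0, "QR": 40.0, "RS": 40.0, "ST": 260.0}
    )
    interval_sds_ms: Mapping[str, float] = field(
        default_factory=lambda: {"PR": 6.0, "QR": 1.5, "RS": 1.5, "ST": 10.0}
    )

    def __post_init__(self) -> None:
        if self.mean_rr_ms <= 0:
            raise ParameterError("mean RR must be > 0 ms")
        if self.sd_rr_ms < 0:
            raise ParameterError("RR sd must be >= 0 ms")
        if not 0.0 <= self.rr_autocorr < 1.0:
            raise ParameterError("RR lag-1 autocorrelation must be in [0, 1)")
        for k in PRIMITIVE_INTERVALS:
            if k not in self.interval_means_ms or k not in self.interval_sds_ms:
                raise ParameterError(f"missing interval entry {k}")
            if self.interval_means_ms[k] <= 0:
                raise ParameterError(f"interval mean {k} must be > 0 ms")
            if self.interval_sds_ms[k] < 0:
                raise ParameterError(f"interval sd {k} must be >= 0 ms")


def rest_condition() -> ConditionParams:
    """Default rest-state condition (RR 800±50 ms, template intervals)."""
    return ConditionParams()


def stress_condition(
    rest: ConditionParams | None = None,
    rr_scale: float = 0.95,
    rr_sd_scale: float = 0.7,
    interval_scale: float = 0.92,
    interval_sd_scale: float = 0.7,
) -> ConditionParams:
    """Stress-state condition derived from a rest condition.

    Acute stress raises heart rate (shorter mean RR), damps RR variability,
    and shortens/tightens the within-beat conduction intervals — every
    interval-based feature then correlates negatively with the stress label.
    """
    if rest is None:
        rest = rest_condition()
    return replace(
        rest,
        mean_rr_ms=rest.mean_rr_ms * rr_scale,
        sd_rr_ms=rest.sd_rr_ms * rr_sd_scale,
        interval_means_ms={k: v * interval_scale for k, v in rest.interval_means_ms.items()},
        interval_sds_ms={k: v * interval_sd_scale for k, v in rest.interval_sds_ms.items()},
    )


@dataclass(frozen=True)
class NoiseParams:
    """Additive recording noise: white sensor noise, baseline wander,
    powerline hum, and sparse motion-artifact bursts.

    The default white-noise level models a noisy wearable recording: after
    the standard low-pass front end the surviving in-band noise is of the
    same order as the Q-wave amplitude, so Q detectability degrades first.
    """

    white_sd_mv: float = 0.1
    baseline_amp_mv: float = 0.05
    baseline_freq_hz: float = 0.25
    powerline_amp_mv: float = 0.01
    powerline_freq_hz: float = 50.0
    burst_rate_per_min: float = 2.0
    burst_amp_mv: float = 0.4

    def __post_init__(self) -> None:
        for name in ("white_sd_mv", "baseline_amp_mv", "powerline_amp_mv", "burst_amp_mv"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("baseline_freq_hz", "powerline_freq_hz"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.burst_rate_per_min < 0:
            raise ParameterError("burst_rate_per_min must be >= 0")


def zero_noise() -> NoiseParams:
    return NoiseParams(
        white_sd_mv=0.0, baseline_amp_mv=0.0, powerline_amp_mv=0.0,
        burst_rate_per_min=0.0, burst_amp_mv=0.0,
    )


@dataclass(frozen=True)
class StudyLayout:
    """Shape of a generated study: participants x (stress + rest) windows."""

    n_participants: int = 57
    n_stress: int = 16
    n_rest: int = 16
    window_s: float = 10.0
    fs: float = 1000.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_stress", "n_rest"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.window_s <= 0:
            raise ParameterError("window_s must be > 0")
        if self.fs < 100.0:
            raise ParameterError("sampling rate must be >= 100 Hz")

    @property
    def n_windows(self) -> int:
        return self.n_participants * (self.n_stress + self.n_rest)
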