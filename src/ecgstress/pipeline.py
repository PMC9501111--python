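"""End-to-end experiment: simulate -> filter -> delineate -> features ->
select -> compare -> benchmark -> score detection.

One call reproduces the whole traditional-vs-novel feature-model workflow on
a synthetic study: the traditional feature model (TFM) selects from the 24
R-peak features, the novel feature model (NFM) from those plus the 12
small-peak features, both by stepwise AIC on the training split; the two
models are then compared by AIC relative likelihood on the reserved test
split and benchmarked with LDA, logistic-regression and SVC classifiers
under stratified 10-fold CV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import delineate as dl
from .errors import DataError
from .features import (
    ALL_FEATURES,
    DEFAULT_BIN_WIDTH_MS,
    NOVEL_FEATURES,
    TRADITIONAL_FEATURES,
    rr_from_peaks,
    window_features,
    zscore_table,
)
from .io import ECGRecord, EventLog
from .models import (
    CVMetrics,
    ModelFit,
    compare_aic,
    correlation_matrix,
    crossval_metrics,
    fit_scored_model,
    stepwise_aic,
    validity_report,
)
from .evaluate import evaluate_study, summarize_scores
from .params import (
    ConditionParams,
    MorphologyParams,
    NoiseParams,
    StudyLayout,
    rest_condition,
    stress_condition,
)
from .preprocess import butterworth_filter, segment_windows
from .simulate import StudyBundle, generate_study, write_study

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a run, serializable to YAML."""

    layout: StudyLayout = field(default_factory=StudyLayout)
    rest: ConditionParams = field(default_factory=rest_condition)
    stress: ConditionParams = field(default_factory=stress_condition)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    filter_order: int = 5
    filter_cutoff: float = 0.3
    filter_btype: str = "lowpass"
    search: dl.SearchConfig = field(default_factory=dl.SearchConfig)
    quality_min_beats: int = 5
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS
    likelihood: str = "binomial"
    split_seed: int = 0
    cv_folds: int = 10
    detection_sample: int = 10
    detection_tolerance_ms: float = 50.0

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: Dict) -> "ExperimentConfig":
        d = dict(d)
        kw = {}
        for name, typ in (
            ("layout", StudyLayout),
            ("rest", ConditionParams),
            ("stress", ConditionParams),
            ("morphology", MorphologyParams),
            ("noise", NoiseParams),
            ("search", dl.SearchConfig),
        ):
            if name in d:
                kw[name] = typ(**d.pop(name))
        kw.update(d)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    n_windows_generated: int
    n_windows_delineated: int
    n_windows_quality: int
    features_raw: pd.DataFrame
    features_scaled: pd.DataFrame
    tfm_fit: ModelFit
    nfm_fit: ModelFit
    tfm_test_aic: float
    nfm_test_aic: float
    aic_comparison: Dict
    validity: pd.DataFrame
    correlations: Dict[str, pd.DataFrame]
    cv_metrics: List[CVMetrics]
    detection_scores: pd.DataFrame
    detection_summary: pd.DataFrame


def extract_feature_table(
    bundle: StudyBundle, config: ExperimentConfig
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, int]]:
    """Filter, delineate and featurize every window of a rendered study.

    Returns the raw feature table, the delineated peak-set frame (for
    detection scoring), and stage window counts.
    """
    fs = bundle.layout.fs
    rows: List[Dict] = []
    det_frames: List[pd.DataFrame] = []
    n_delineated = 0
    for part in bundle.participants:
        if part.signal is None:
            raise DataError("study bundle was generated without signals (render=False)")
        record = ECGRecord(pid=part.pid, fs=fs, samples=part.signal)
        record = butterworth_filter(
            record, config.filter_order, config.filter_cutoff, config.filter_btype
        )
        log = EventLog(entries=[tuple(r) for r in part.events.itertuples(index=False)])
        windows = segment_windows(record, log, bundle.layout.window_s)
        for k, win in enumerate(windows):
            wid = f"{part.pid}-{k:02d}"
            r_peaks = dl.detect_r_peaks(win, fs, config.search.refractory_s)
            if r_peaks.size < 2:
                continue
            peaks = dl.delineate_waves(win, fs, r_peaks, config.search)
            det_frames.append(peaks.to_frame(wid, part.pid))
            n_delineated += 1
            if not dl.window_quality(peaks, min_beats=config.quality_min_beats):
                continue
            try:
                rr = rr_from_peaks(r_peaks, fs)
                feats = window_features(rr, peaks, fs, config.bin_width_ms)
            except DataError:
                continue
            if any(not np.isfinite(v) for v in feats.values()):
                continue
            feats.update({"pid": part.pid, "window_id": wid, "stress": win.label})
            rows.append(feats)
    table = pd.DataFrame(rows)
    detections = (
        pd.concat(det_frames, ignore_index=True)
        if det_frames
        else pd.DataFrame(
            columns=["participant", "window_id", "beat", "wave", "sample_index", "present"]
        )
    )
    counts = {
        "generated": bundle.n_windows,
        "delineated": n_delineated,
        "quality": len(table),
    }
    logger.info("window accounting: %s", counts)
    return table, detections, counts


def run_experiment(
    config: Optional[ExperimentConfig] = None,
    outdir: Optional[Path] = None,
    bundle: Optional[StudyBundle] = None,
    write_signals: bool = False,
) -> ExperimentResult:
    """Run the full TFM-vs-NFM comparison; optionally write all artifacts."""
    config = config or ExperimentConfig()
    if bundle is None:
        bundle = generate_study(
            config.layout, config.rest, config.stress, config.morphology, config.noise
        )
    table, detections, counts = extract_feature_table(bundle, config)
    if len(table) < 20:
        raise DataError(f"only {len(table)} windows survived quality filtering")
    meta = ["pid", "window_id", "stress"]
    table = table[meta + list(ALL_FEATURES)]
    scaled = zscore_table(table, columns=list(ALL_FEATURES))

    idx_train, idx_test = train_test_split(
        np.arange(len(scaled)),
        test_size=0.33,
        random_state=config.split_seed,
        stratify=scaled["stress"],
    )
    train, test = scaled.iloc[idx_train], scaled.iloc[idx_test]

    tfm_fit = stepwise_aic(train, TRADITIONAL_FEATURES, config.likelihood)
    nfm_fit = stepwise_aic(train, ALL_FEATURES, config.likelihood)
    tfm_test = fit_scored_model(test, tfm_fit.features, config.likelihood)
    nfm_test = fit_scored_model(test, nfm_fit.features, config.likelihood)
    comparison = compare_aic(tfm_test.aic, nfm_test.aic, "TFM", "NFM")

    validity = validity_report(scaled, ALL_FEATURES)
    correlations = {
        "tfm": correlation_matrix(scaled, tfm_fit.features or TRADITIONAL_FEATURES[:2]),
        "novel": correlation_matrix(
            scaled, [f for f in nfm_fit.features if f in NOVEL_FEATURES] or list(NOVEL_FEATURES)
        ),
        "union": correlation_matrix(
            scaled, sorted(set(tfm_fit.features) | set(nfm_fit.features)) or list(ALL_FEATURES)
        ),
    }

    cv_results: List[CVMetrics] = []
    for name, feats in (("TFM", tfm_fit.features), ("NFM", nfm_fit.features)):
        feats = list(feats) or (
            list(TRADITIONAL_FEATURES) if name == "TFM" else list(ALL_FEATURES)
        )
        for algo in ("LDA", "LR", "SVC"):
            cv = crossval_metrics(
                scaled, feats, algo, k=config.cv_folds,
                split_seed=config.split_seed, select=False,
            )
            cv.algorithm = f"{name}-{algo}"
            cv_results.append(cv)

    fs = bundle.layout.fs
    n_win = int(round(bundle.layout.window_s * fs))
    margin = (
        int(round(config.search.p_lookback_ms * fs / 1000.0)),
        n_win - int(round(config.search.t_lookahead_ms * fs / 1000.0)),
    )
    det_scores = evaluate_study(
        detections,
        bundle.ground_truth_frame(),
        fs,
        n_participants_sample=config.detection_sample,
        seed=config.split_seed,
        tolerance_ms=config.detection_tolerance_ms,
        valid_range=margin,
    )
    det_summary = summarize_scores(det_scores)

    result = ExperimentResult(
        config=config,
        n_windows_generated=counts["generated"],
        n_windows_delineated=counts["delineated"],
        n_windows_quality=counts["quality"],
        features_raw=table,
        features_scaled=scaled,
        tfm_fit=tfm_fit,
        nfm_fit=nfm_fit,
        tfm_test_aic=tfm_test.aic,
        nfm_test_aic=nfm_test.aic,
        aic_comparison=comparison,
        validity=validity,
        correlations=correlations,
        cv_metrics=cv_results,
        detection_scores=det_scores,
        detection_summary=det_summary,
    )
    if outdir is not None:
        _write_artifacts(result, bundle, Path(outdir), write_signals)
    return result


def _histogram_frame(table: pd.DataFrame, features, bins: int = 20) -> pd.DataFrame:
    rows = []
    for f in features:
        vals = table[f].to_numpy(dtype=float)
        edges = np.histogram_bin_edges(vals, bins=bins)
        for label in (0, 1):
            counts, _ = np.histogram(vals[table["stress"] == label], bins=edges)
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                rows.append((f, label, lo, hi, int(c)))
    return pd.DataFrame(rows, columns=["feature", "stress", "bin_lo", "bin_hi", "count"])


def _write_artifacts(
    result: ExperimentResult, bundle: StudyBundle, outdir: Path, write_signals: bool
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    cfg.to_yaml(outdir / "config.yaml")
    result.features_raw.to_csv(outdir / "features.csv", index=False)
    result.features_scaled.to_csv(outdir / "features_scaled.csv", index=False)

    rpb = dict(zip(result.validity["feature"], result.validity["r_pb"]))
    report_rows = []
    for name, fit in (("TFM", result.tfm_fit), ("NFM", result.nfm_fit)):
        for f in fit.features:
            report_rows.append(
                (name, f, fit.params[f], fit.pvalues[f], rpb.get(f, float("nan")))
            )
    pd.DataFrame(report_rows, columns=["model", "feature", "beta", "p", "r_pb"]).to_csv(
        outdir / "model_report.csv", index=False
    )

    metric_rows = []
    for cv in result.cv_metrics:
        for m, (mean, sd) in cv.metrics.items():
            metric_rows.append((cv.algorithm, m, mean, sd))
    pd.DataFrame(metric_rows, columns=["model", "metric", "mean", "sd"]).to_csv(
        outdir / "metrics.csv", index=False
    )
    for name, mat in result.correlations.items():
        mat.to_csv(outdir / f"correlations_{name}.csv")
    _histogram_frame(result.features_raw, ALL_FEATURES).to_csv(
        outdir / "histograms.csv", index=False
    )
    result.detection_scores.to_csv(outdir / "detection_scores.csv", index=False)
    result.detection_summary.to_csv(outdir / "detection_summary.csv", index=False)
    if write_signals:
        write_study(bundle, outdir / "study")

    lines = [
        f"config hash: {cfg.config_hash()}",
        f"windows generated / delineated / quality: "
        f"{result.n_windows_generated} / {result.n_windows_delineated} / "
        f"{result.n_windows_quality}",
        f"TFM selected ({len(result.tfm_fit.features)}): {', '.join(result.tfm_fit.features)}",
        f"NFM selected ({len(result.nfm_fit.features)}): {', '.join(result.nfm_fit.features)}",
        f"test AIC: TFM {result.tfm_test_aic:.2f}, NFM {result.nfm_test_aic:.2f}",
        f"relative likelihood: {result.aic_comparison['statement']}",
    ]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
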