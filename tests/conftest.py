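import numpy as np
import pytest

import ecgstress as es


@pytest.fixture(scope="session")
def clean_window():
    """One zero-noise 10 s window at 1000 Hz with its ground truth."""
    cond = es.rest_condition()
    rr = es.generate_rr_series(cond, 12, 11)
    sig, gt = es.synthesize_window(
        rr, es.MorphologyParams(), cond, es.zero_noise(), 1000.0, 12
    )
    return sig, gt


@pytest.fixture(scope="session")
def clean_study():
    """Small zero-noise rendered study at 500 Hz."""
    layout = es.StudyLayout(n_participants=5, n_stress=4, n_rest=4, fs=500.0, master_seed=21)
    return es.generate_study(layout, noise=es.zero_noise())


@pytest.fixture(scope="session")
def noisy_study():
    """Small default-noise rendered study at 500 Hz."""
    layout = es.StudyLayout(n_participants=14, n_stress=8, n_rest=8, fs=500.0, master_seed=5)
    return es.generate_study(layout)


@pytest.fixture(scope="session")
def truth_table():
    """Feature table from planted annotations of a moderately large study."""
    from helpers import feature_table_from_truth

    layout = es.StudyLayout(n_participants=16, n_stress=8, n_rest=8, fs=1000.0, master_seed=33)
    bundle = es.generate_study(layout, render=False)
    return feature_table_from_truth(bundle)


def study_margin(layout: es.StudyLayout, cfg: es.SearchConfig | None = None):
    """Sample range inside a window where the delineator is defined."""
    cfg = cfg or es.SearchConfig()
    n = int(round(layout.window_s * layout.fs))
    return (
        int(round(cfg.p_lookback_ms * layout.fs / 1000.0)),
        n - int(round(cfg.t_lookahead_ms * layout.fs / 1000.0)),
    )


def delineate_study(bundle, config: es.ExperimentConfig | None = None):
    from ecgstress.pipeline import ExperimentConfig, extract_feature_table

    config = config or es.ExperimentConfig(layout=bundle.layout)
    return extract_feature_table(bundle, config)
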