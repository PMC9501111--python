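import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ecgstress as es
from ecgstress.errors import DataError
from ecgstress.features import ALL_FEATURES, TRADITIONAL_FEATURES
from helpers import feature_table_from_truth


def _noise_table(n=500, n_features=6, beta=2.0, seed=0):
    """label ~ Bernoulli(logistic(beta * x1)); x2..x6 pure noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    p = 1.0 / (1.0 + np.exp(-beta * X[:, 0]))
    y = (rng.uniform(size=n) < p).astype(int)
    cols = {f"x{i + 1}": X[:, i] for i in range(n_features)}
    cols["stress"] = y
    return pd.DataFrame(cols)


class TestFitScoredModel:
    def test_intercept_only_binomial_closed_form(self):
        t = pd.DataFrame({"stress": [0] * 6 + [1] * 6})
        fit = es.fit_scored_model(t, [], "binomial")
        assert fit.llf == pytest.approx(12 * np.log(0.5), rel=1e-9)
        assert fit.k == 1
        assert fit.aic == pytest.approx(2 - 24 * np.log(0.5), rel=1e-9)

    def test_pure_noise_column_raises_aic_at_most_2(self):
        t = _noise_table(seed=5)
        base = es.fit_scored_model(t, [], "binomial")
        plus = es.fit_scored_model(t, ["x6"], "binomial")
        assert plus.aic <= base.aic + 2.0 + 1e-6

    def test_gaussian_k_counts_residual_variance(self):
        t = _noise_table(seed=1)
        fit = es.fit_scored_model(t, ["x1", "x2"], "gaussian")
        assert fit.k == 4
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.llf)

    def test_degenerate_gaussian_fit_rejected(self):
        t = _noise_table(n=50, seed=2)
        t["leak"] = t["stress"].astype(float)
        with pytest.raises(DataError):
            es.fit_scored_model(t, ["leak"], "gaussian")

    def test_perfect_separation_flagged_not_fatal(self):
        t = _noise_table(n=50, seed=3)
        t["leak"] = t["stress"].astype(float) * 2 - 1
        fit = es.fit_scored_model(t, ["leak"], "binomial")
        assert fit.separation
        assert np.isfinite(fit.aic)

    def test_singular_design_rejected(self):
        t = _noise_table(n=50, seed=4)
        t["dup"] = t["x1"]
        with pytest.raises(DataError):
            es.fit_scored_model(t, ["x1", "dup"], "binomial")


class TestStepwiseAIC:
    def test_empty_candidates_gives_intercept_only(self):
        t = _noise_table(seed=6)
        fit = es.stepwise_aic(t, [], "binomial")
        assert fit.features == ()
        assert fit.k == 1

    def test_matches_exhaustive_best_subset(self):
        t = _noise_table(n=500, n_features=6, seed=7)
        candidates = [f"x{i}" for i in range(1, 7)]
        step = es.stepwise_aic(t, candidates, "binomial")
        best_aic, best_set = np.inf, None
        for r in range(len(candidates) + 1):
            for subset in itertools.combinations(candidates, r):
                aic = es.fit_scored_model(t, list(subset), "binomial").aic
                if aic < best_aic - 1e-10:
                    best_aic, best_set = aic, set(subset)
        assert set(step.features) == best_set
        assert "x1" in step.features
        assert step.aic == pytest.approx(best_aic)

    def test_never_worse_than_intercept_only(self):
        t = _noise_table(n=200, beta=0.0, seed=8)  # null: label independent
        fit = es.stepwise_aic(t, [f"x{i}" for i in range(1, 7)], "binomial")
        null = es.fit_scored_model(t, [], "binomial")
        assert fit.aic <= null.aic + 1e-9

    def test_aic_path_strictly_decreasing(self):
        t = _noise_table(seed=9)
        sel = es.StepwiseAIC(candidates=[f"x{i}" for i in range(1, 7)])
        sel.fit(t[[c for c in t.columns if c != "stress"]], t["stress"])
        path = np.array(sel.aic_path_)
        assert np.all(np.diff(path) < 0)

    def test_sklearn_estimator_interface(self):
        t = _noise_table(seed=10)
        sel = es.StepwiseAIC(candidates=["x1", "x2", "x3"])
        assert sel.get_params()["likelihood"] == "binomial"
        sel.fit(t[["x1", "x2", "x3"]], t["stress"])
        out = sel.transform(t[["x1", "x2", "x3"]])
        assert list(out.columns) == list(sel.selected_features_)


class TestPointBiserial:
    def test_feature_equal_to_labels(self):
        r, p = es.point_biserial([0, 0, 1, 1, 0, 1], [0, 0, 1, 1, 0, 1])
        assert r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        r, _ = es.point_biserial([1, 2, 3, 4], [0, 0, 1, 1])
        assert r == pytest.approx(0.8944, abs=1e-4)

    def test_agrees_with_pearson_on_binary(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=60)
            y = rng.integers(0, 2, size=60)
            if y.min() == y.max():
                continue
            ours, p_ours = es.point_biserial(x, y)
            ref, p_ref = stats.pointbiserialr(y, x)
            assert ours == pytest.approx(ref, abs=1e-12)
            assert p_ours == pytest.approx(p_ref, rel=1e-9)

    def test_permutation_null_centred_on_zero(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=100)
        y = np.array([0] * 50 + [1] * 50)
        rs = []
        for _ in range(1000):
            rs.append(es.point_biserial(x, rng.permutation(y))[0])
        null_se = 1.0 / np.sqrt(100 - 1)
        assert abs(np.mean(rs)) < 3 * null_se / np.sqrt(1000)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            es.point_biserial([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(DataError):
            es.point_biserial([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])


class TestRelativeLikelihood:
    def test_equal_aics_give_one(self):
        assert es.relative_likelihood(-100.0, -100.0) == 1.0

    def test_definition_at_delta_two(self):
        assert es.relative_likelihood(0.0, 2.0) == pytest.approx(np.exp(-1.0))

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a, b = rng.normal(0, 50, 2)
            r1, r2 = es.relative_likelihood(a, b), es.relative_likelihood(b, a)
            assert r1 == r2
            assert 0.0 < r1 <= 1.0

    def test_orientation_reported(self):
        cmp = es.compare_aic(-2105.24, -2237.1, "TFM", "NFM")
        assert cmp["worse"] == "TFM" and cmp["better"] == "NFM"


class TestCorrelationMatrix:
    def test_structure(self):
        rng = np.random.default_rng(14)
        t = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        t["c"] = -t["a"]
        m = es.correlation_matrix(t, ["a", "b", "c"])
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m, m.T)
        assert m.loc["a", "c"] == pytest.approx(-1.0)

    def test_constant_column_rejected(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(DataError):
            es.correlation_matrix(t, ["a", "b"])


class TestCrossvalMetrics:
    def test_separable_data_perfect_scores(self):
        rng = np.random.default_rng(15)
        n = 200
        y = np.repeat([0, 1], n // 2)
        t = pd.DataFrame(
            {
                "f1": y * 10.0 + rng.normal(0, 0.1, n),
                "f2": rng.normal(size=n),
                "stress": y,
            }
        )
        for algo in ("LDA", "LR", "SVC"):
            cv = es.crossval_metrics(t, ["f1", "f2"], algo, k=5, select=False)
            assert cv.metrics["accuracy"][0] == pytest.approx(1.0)
            assert cv.metrics["accuracy"][1] == pytest.approx(0.0, abs=1e-12)

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(16)
        n = 1000
        t = pd.DataFrame(
            {
                "f1": rng.normal(size=n),
                "f2": rng.normal(size=n),
                "stress": rng.integers(0, 2, size=n),
            }
        )
        cv = es.crossval_metrics(t, ["f1", "f2"], "LR", k=10, split_seed=1, select=False)
        # binomial 99% envelope around 0.5 on the CV rows
        half_width = 2.58 * 0.5 / np.sqrt(cv.n_cv_rows)
        assert abs(cv.metrics["accuracy"][0] - 0.5) < 3 * half_width

    def test_nfm_superset_not_worse_on_planted_effect(self):
        layout = es.StudyLayout(n_participants=10, n_stress=10, n_rest=10, fs=1000.0, master_seed=55)
        table = feature_table_from_truth(es.generate_study(layout, render=False))
        z = es.zscore_table(table, columns=list(ALL_FEATURES))
        for algo in ("LDA", "LR", "SVC"):
            tfm = es.crossval_metrics(z, list(TRADITIONAL_FEATURES), algo, k=5, select=True)
            nfm = es.crossval_metrics(z, list(ALL_FEATURES), algo, k=5, select=True)
            assert nfm.metrics["accuracy"][0] >= tfm.metrics["accuracy"][0] - 0.02

    def test_too_small_minority_class_rejected(self):
        t = pd.DataFrame({"f1": np.arange(30.0), "stress": [0] * 27 + [1] * 3})
        with pytest.raises(DataError):
            es.crossval_metrics(t, ["f1"], "LR", k=10, select=False)
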