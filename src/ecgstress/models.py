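"""Feature validity, stepwise-AIC model selection, and classifier benchmarks.

The scientific core: two candidate pools — 24 traditional R-peak features
(the TFM pool) and those plus 12 small-peak features (the NFM pool) — are
each reduced by bidirectional stepwise search minimising AIC = 2k - 2 logL.
Fitted models are compared through the AIC relative likelihood
exp((AIC_min - AIC_max) / 2): the probability, relative to the better model,
that the worse one minimises information loss. Per-feature validity is the
point-biserial correlation between the feature and the binary stress label.

The selection likelihood is binomial (logistic regression) by default; a
gaussian option fits an OLS linear-probability model instead, whose AIC can
be large and negative when residuals are small.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import DataError, ParameterError

LABEL_COLUMN = "stress"

_AIC_TOL = 1e-10


@dataclass
class ModelFit:
    """A fitted stress model: selected features, coefficients, and AIC."""

    features: Tuple[str, ...]
    params: Dict[str, float]
    pvalues: Dict[str, float]
    llf: float
    k: int
    aic: float
    likelihood: str
    nobs: int
    separation: bool = False

    def __post_init__(self) -> None:
        assert abs(self.aic - (2 * self.k - 2 * self.llf)) < 1e-6


def fit_scored_model(
    table: pd.DataFrame,
    features: Sequence[str],
    likelihood: str = "binomial",
    label_col: str = LABEL_COLUMN,
) -> ModelFit:
    """Maximum-likelihood fit of the label on the given (z-scored) features.

    binomial: logistic regression, k = #features + 1 (intercept).
    gaussian: OLS linear-probability model, k = #features + 2 (intercept and
    residual variance).

    Perfect separation under the binomial likelihood is flagged: the fit is
    retried with a light ridge penalty, p-values are NaN, and
    ``separation=True`` on the result.
    """
    if likelihood not in ("binomial", "gaussian"):
        raise ParameterError(f"unknown likelihood {likelihood!r}")
    features = list(features)
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ParameterError(f"features not in table: {missing}")
    if len(table) < 10:
        raise DataError("need at least 10 rows to fit a stress model")
    y = table[label_col].to_numpy(dtype=float)
    X = sm.add_constant(table[features].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("singular design matrix (collinear or constant features)")

    names = ["const"] + features
    if likelihood == "gaussian":
        res = sm.OLS(y, X).fit()
        if res.ssr <= 1e-12 * len(y):
            raise DataError("degenerate gaussian fit: zero residual variance")
        llf, k = float(res.llf), len(features) + 2
        params = dict(zip(names, res.params))
        pvals = dict(zip(names, res.pvalues))
        sep = False
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
                if not np.all(np.isfinite(res.bse)) or not np.isfinite(res.llf):
                    raise PerfectSeparationError("non-finite standard errors or likelihood")
                if res.llf > -1e-6 * len(y):
                    # likelihood at its supremum: the classes are separated
                    raise PerfectSeparationError("log-likelihood at zero")
                llf = float(res.llf)
                params = dict(zip(names, res.params))
                pvals = dict(zip(names, res.pvalues))
            sep = False
        except (PerfectSeparationError, np.linalg.LinAlgError):
            clf = LogisticRegression(C=1e4, max_iter=5000)
            clf.fit(X[:, 1:] if features else np.zeros((len(y), 1)), y)
            prob = np.clip(clf.predict_proba(X[:, 1:] if features else np.zeros((len(y), 1)))[:, 1],
                           1e-12, 1 - 1e-12)
            llf = float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
            params = dict(zip(names, np.concatenate([clf.intercept_, clf.coef_.ravel()])))
            pvals = {n: float("nan") for n in names}
            sep = True
        if not np.isfinite(llf):
            raise DataError("binomial log-likelihood is not finite")
        k = len(features) + 1
    return ModelFit(
        features=tuple(features),
        params={n: float(v) for n, v in params.items()},
        pvalues={n: float(v) for n, v in pvals.items()},
        llf=llf,
        k=k,
        aic=2 * k - 2 * llf,
        likelihood=likelihood,
        nobs=len(y),
        separation=sep,
    )


class StepwiseAIC(BaseEstimator, TransformerMixin):
    """Bidirectional stepwise feature selection minimising AIC.

    Starting from the empty set, every single addition and single removal is
    scored at each iteration and the move with the lowest resulting AIC is
    applied, stopping when no move lowers the AIC. Deterministic given the
    data; ties are broken by candidate order. sklearn-compatible: ``fit`` on
    a feature DataFrame and a binary label, ``transform`` keeps the selected
    columns.
    """

    def __init__(self, candidates: Optional[Sequence[str]] = None, likelihood: str = "binomial"):
        self.candidates = candidates
        self.likelihood = likelihood

    def fit(self, X: pd.DataFrame, y: Sequence[int]):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=[f"x{i}" for i in range(np.shape(X)[1])])
        candidates = list(self.candidates) if self.candidates is not None else list(X.columns)
        unknown = [c for c in candidates if c not in X.columns]
        if unknown:
            raise ParameterError(f"candidates not in table: {unknown}")
        table = X.copy()
        table[LABEL_COLUMN] = np.asarray(y)

        def score(feats: List[str]) -> Optional[ModelFit]:
            try:
                return fit_scored_model(table, feats, self.likelihood)
            except DataError:
                return None

        selected: List[str] = []
        current = score(selected)
        if current is None:
            raise DataError("intercept-only model could not be fitted")
        path: List[float] = [current.aic]
        while True:
            moves: List[Tuple[str, str]] = [("add", f) for f in candidates if f not in selected]
            moves += [("remove", f) for f in selected]
            best: Optional[Tuple[ModelFit, List[str]]] = None
            for op, f in moves:
                trial = selected + [f] if op == "add" else [g for g in selected if g != f]
                fit = score(trial)
                if fit is None:
                    continue
                if best is None or fit.aic < best[0].aic - _AIC_TOL:
                    best = (fit, trial)
            if best is None or best[0].aic >= current.aic - _AIC_TOL:
                break
            current, selected = best[0], best[1]
            path.append(current.aic)

        self.selected_features_ = tuple(selected)
        self.model_fit_ = current
        self.aic_path_ = tuple(path)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "selected_features_"):
            raise DataError("StepwiseAIC is not fitted")
        return X[list(self.selected_features_)]


def stepwise_aic(
    table: pd.DataFrame,
    candidates: Sequence[str],
    likelihood: str = "binomial",
    label_col: str = LABEL_COLUMN,
) -> ModelFit:
    """Functional wrapper over :class:`StepwiseAIC`; returns the final fit."""
    sel = StepwiseAIC(candidates=list(candidates), likelihood=likelihood)
    sel.fit(table[[c for c in table.columns if c != label_col]], table[label_col])
    return sel.model_fit_


def point_biserial(values: Sequence[float], labels: Sequence[int]) -> Tuple[float, float]:
    """Point-biserial validity coefficient and its two-sided p-value.

    r_pb = ((M1 - M0) / s_n) * sqrt(n1 n0 / n^2) with s_n the population sd;
    identical to the Pearson correlation with the 0/1 label coding. p comes
    from the t transform with n - 2 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if x.size != y.size or x.size < 3:
        raise DataError("need matched value/label arrays with n >= 3")
    n1, n0 = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise DataError("both classes must be present")
    s = x.std(ddof=0)
    if s == 0:
        raise DataError("feature is constant")
    n = x.size
    r = ((x[y == 1].mean() - x[y == 0].mean()) / s) * math.sqrt(n1 * n0 / (n * n))
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    from scipy import stats as _st

    p = 2.0 * _st.t.sf(abs(t), df=n - 2)
    return float(r), float(p)


def validity_report(
    table: pd.DataFrame, features: Sequence[str], label_col: str = LABEL_COLUMN
) -> pd.DataFrame:
    """Point-biserial r and p for each feature against the stress label."""
    rows = []
    for f in features:
        r, p = point_biserial(table[f], table[label_col])
        rows.append((f, r, p))
    return pd.DataFrame(rows, columns=["feature", "r_pb", "p"])


def relative_likelihood(aic_a: float, aic_b: float) -> float:
    """AIC relative likelihood exp((AIC_min - AIC_max) / 2), in (0, 1].

    Read as: the worse (higher-AIC) model is this many times as probable as
    the better one to minimise information loss. Symmetric in its arguments.
    """
    if not (np.isfinite(aic_a) and np.isfinite(aic_b)):
        raise ParameterError("AIC values must be finite")
    return math.exp((min(aic_a, aic_b) - max(aic_a, aic_b)) / 2.0)


def compare_aic(aic_a: float, aic_b: float, name_a: str = "A", name_b: str = "B") -> Dict:
    """Oriented AIC comparison of two models."""
    ratio = relative_likelihood(aic_a, aic_b)
    worse, better = (name_a, name_b) if aic_a >= aic_b else (name_b, name_a)
    return {
        "ratio": ratio,
        "worse": worse,
        "better": better,
        "statement": f"{worse} is {ratio:.3g} times as probable as {better} "
        "to minimise information loss",
    }


def correlation_matrix(table: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    """Pearson correlation matrix of the given feature columns."""
    if len(table) < 3:
        raise DataError("need at least 3 rows for a correlation matrix")
    sub = table[list(features)].astype(float)
    if (sub.std(ddof=1) == 0).any():
        bad = sub.columns[(sub.std(ddof=1) == 0)].tolist()
        raise DataError(f"constant columns: {bad}")
    return sub.corr()


_CLASSIFIERS = {
    "LDA": lambda: LinearDiscriminantAnalysis(),
    "LR": lambda: LogisticRegression(max_iter=5000),
    "SVC": lambda: SVC(),
}


@dataclass
class CVMetrics:
    """Mean +/- sd of classification metrics over stratified CV folds."""

    algorithm: str
    features: Tuple[str, ...]
    metrics: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    n_cv_rows: int = 0


def crossval_metrics(
    table: pd.DataFrame,
    features: Sequence[str],
    algorithm: str,
    k: int = 10,
    split_seed: int = 0,
    likelihood: str = "binomial",
    select: bool = True,
    cv_scope: str = "test",
    label_col: str = LABEL_COLUMN,
) -> CVMetrics:
    """Benchmark one classifier on a feature set under stratified k-fold CV.

    The table is first split 67/33 (stratified); when ``select`` is true,
    stepwise AIC selection runs on the training portion and the selected set
    is what the classifier sees. CV folds are then drawn from the reserved
    test portion (``cv_scope="test"``, the default) or from the full table
    (``cv_scope="full"``).
    """
    if algorithm not in _CLASSIFIERS:
        raise ParameterError(f"unknown algorithm {algorithm!r}; pick from {sorted(_CLASSIFIERS)}")
    if cv_scope not in ("test", "full"):
        raise ParameterError("cv_scope must be 'test' or 'full'")
    y = table[label_col].to_numpy()
    idx_train, idx_test = train_test_split(
        np.arange(len(table)), test_size=0.33, random_state=split_seed, stratify=y
    )
    if select:
        fit = stepwise_aic(table.iloc[idx_train], features, likelihood, label_col)
        used = list(fit.features) if fit.features else list(features)
    else:
        used = list(features)

    cv_idx = idx_test if cv_scope == "test" else np.arange(len(table))
    Xc = table.iloc[cv_idx][used].to_numpy(dtype=float)
    yc = y[cv_idx]
    counts = np.bincount(yc.astype(int), minlength=2)
    if counts.min() < k:
        raise DataError(
            f"cannot form {k} stratified folds: minority class has {counts.min()} rows"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=split_seed)
    scores: Dict[str, List[float]] = {m: [] for m in ("precision", "recall", "f1", "auc", "accuracy")}
    for tr, te in skf.split(Xc, yc):
        clf = _CLASSIFIERS[algorithm]()
        clf.fit(Xc[tr], yc[tr])
        pred = clf.predict(Xc[te])
        if hasattr(clf, "decision_function"):
            score = clf.decision_function(Xc[te])
        else:
            score = clf.predict_proba(Xc[te])[:, 1]
        scores["precision"].append(precision_score(yc[te], pred, zero_division=0))
        scores["recall"].append(recall_score(yc[te], pred, zero_division=0))
        scores["f1"].append(f1_score(yc[te], pred, zero_division=0))
        scores["accuracy"].append(accuracy_score(yc[te], pred))
        scores["auc"].append(
            roc_auc_score(yc[te], score) if len(np.unique(yc[te])) > 1 else float("nan")
        )
    return CVMetrics(
        algorithm=algorithm,
        features=tuple(used),
        metrics={
            m: (float(np.nanmean(v)), float(np.nanstd(v, ddof=0))) for m, v in scores.items()
        },
        n_cv_rows=len(cv_idx),
    )
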