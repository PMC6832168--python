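"""Classification stage: robust scaling, feature selection, ensemble learning.

The stage evaluates six ensemble learners (random forest, extra trees,
gradient boosting, and AdaBoost over SVM / decision-tree / naive-Bayes base
learners) combined with six feature-selection strategies (recursive feature
elimination, chi-squared and univariate-F statistical filters, and
model-based selection by random-forest, extra-trees or linear-SVM
importances).  Evaluation is stratified 10-fold cross-validation; scaling and
selection are fitted inside each training fold only, so no information leaks
from the test folds.  Hyperparameters may be tuned per fold by an inner grid
search, or fixed.

Everything here stands on scikit-learn estimators wired into a Pipeline.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import (
    RFE,
    SelectFromModel,
    SelectorMixin,
    chi2,
    f_classif,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import RobustScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "LEARNERS",
    "SELECTION_METHODS",
    "ModelSpec",
    "SelectionSpec",
    "EvalResult",
    "scale_features",
    "select_features",
    "tune_and_evaluate",
]

LEARNERS = (
    "random_forest",
    "extra_trees",
    "gradient_boost",
    "adaboost_svm",
    "adaboost_tree",
    "adaboost_nb",
)

SELECTION_METHODS = ("rfe", "chi2", "ptest", "model_rf", "model_etc", "model_svm", "none")

# Search ranges centred on the printed per-learner optima of the reference
# tuning tables.
DEFAULT_GRIDS = {
    "random_forest": {
        "clf__n_estimators": list(range(11, 102, 10)),
        "clf__max_depth": list(range(11, 52, 10)),
        "clf__max_features": list(range(2, 11, 2)),
    },
    "extra_trees": {
        "clf__n_estimators": list(range(11, 102, 10)),
        "clf__max_depth": list(range(11, 52, 10)),
        "clf__max_features": list(range(2, 11, 2)),
    },
    "gradient_boost": {
        "clf__n_estimators": list(range(11, 102, 20)),
        "clf__learning_rate": [0.05, 0.1, 0.2, 0.5],
    },
}


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """An ensemble learner plus fixed hyperparameters and an optional grid."""

    learner: str = "extra_trees"
    params: dict = dataclasses.field(default_factory=dict)
    grid: dict | None = None  # GridSearchCV param grid ('clf__' prefixes)

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}; choose from {LEARNERS}")
        if self.grid is not None and not self.grid:
            raise ValueError("grid must be non-empty when tuning is requested")

    def make_learner(self, seed: int | None = None) -> BaseEstimator:
        params = dict(self.params)
        if self.learner == "random_forest":
            return RandomForestClassifier(random_state=seed, **params)
        if self.learner == "extra_trees":
            return ExtraTreesClassifier(random_state=seed, **params)
        if self.learner == "gradient_boost":
            return GradientBoostingClassifier(random_state=seed, **params)
        if self.learner == "adaboost_svm":
            base = SVC(C=1.0, degree=3, gamma="auto", kernel="rbf", probability=True,
                       random_state=seed)
            params.setdefault("n_estimators", 1)
            return AdaBoostClassifier(estimator=base, random_state=seed, **params)
        if self.learner == "adaboost_tree":
            params.setdefault("n_estimators", 40)
            params.setdefault("learning_rate", 1.0)
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(random_state=seed),
                random_state=seed,
                **params,
            )
        if self.learner == "adaboost_nb":
            params.setdefault("n_estimators", 12)
            params.setdefault("learning_rate", 1.3)
            return AdaBoostClassifier(estimator=GaussianNB(), random_state=seed, **params)
        raise AssertionError("unreachable")


@dataclasses.dataclass(frozen=True)
class SelectionSpec:
    """A feature-selection strategy.

    ``threshold`` applies to the statistical filters (chi2 statistic, or the
    univariate-F p-value for ``ptest``); ``n_features`` applies to RFE.
    ``keep_above`` flips the p-value filter to retain features ABOVE the
    threshold (the counter-intuitive literal reading of a ">0.1 p-test").
    """

    method: str = "none"
    threshold: float | None = None
    n_features: int | None = None
    keep_above: bool = False

    def __post_init__(self) -> None:
        if self.method not in SELECTION_METHODS:
            raise ValueError(
                f"unknown selection method {self.method!r}; choose from {SELECTION_METHODS}"
            )
        if self.method == "rfe" and not self.n_features:
            raise ValueError("rfe requires n_features")
        if self.method in ("chi2", "ptest") and self.threshold is None:
            raise ValueError(f"{self.method} requires a threshold")


class _StatFilter(SelectorMixin, BaseEstimator):
    """Univariate filter keeping features by chi2 statistic or F-test p-value.

    For chi2, each column is shifted to be non-negative (min-subtraction)
    before the statistic is computed, since robust-scaled features can be
    negative.
    """

    def __init__(self, kind: str = "chi2", threshold: float = 0.1,
                 keep_above: bool = False):
        self.kind = kind
        self.threshold = threshold
        self.keep_above = keep_above

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if self.kind == "chi2":
            stats, _ = chi2(X - X.min(axis=0), y)
            stats = np.nan_to_num(stats, nan=0.0)
            self.support_ = stats > self.threshold
        elif self.kind == "ptest":
            _, pvals = f_classif(X, y)
            pvals = np.nan_to_num(pvals, nan=1.0)
            if self.keep_above:
                self.support_ = pvals > self.threshold
            else:
                self.support_ = pvals < self.threshold
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_


class _PassThrough(SelectorMixin, BaseEstimator):
    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def _get_support_mask(self):
        return np.ones(self.n_features_in_, dtype=bool)


def _make_selector(spec: SelectionSpec, seed: int | None, learner: BaseEstimator):
    if spec.method == "none":
        return _PassThrough()
    if spec.method == "rfe":
        return RFE(clone(learner), n_features_to_select=spec.n_features)
    if spec.method == "chi2":
        return _StatFilter("chi2", spec.threshold)
    if spec.method == "ptest":
        return _StatFilter("ptest", spec.threshold, keep_above=spec.keep_above)
    if spec.method == "model_rf":
        return SelectFromModel(RandomForestClassifier(random_state=seed), threshold="mean")
    if spec.method == "model_etc":
        return SelectFromModel(ExtraTreesClassifier(random_state=seed), threshold="mean")
    if spec.method == "model_svm":
        return SelectFromModel(
            LinearSVC(C=1.0, dual=False, random_state=seed), threshold="mean"
        )
    raise AssertionError("unreachable")


@dataclasses.dataclass
class EvalResult:
    mean_accuracy: float  # percent
    accuracy_sd: float  # percent
    fold_accuracies: list[float]  # percent, one per fold
    chosen_params: dict
    selected_features: list[str]

    def __str__(self) -> str:  # "mean%(SD%)" convention
        return f"{self.mean_accuracy:.2f}%({self.accuracy_sd:.2f}%)"


def _split_table(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    meta = [c for c in ("subject", "label") if c in table.columns]
    if "label" not in meta:
        raise ValueError("feature table needs a 'label' column")
    features = [c for c in table.columns if c not in meta]
    return table[features], table["label"], features


def scale_features(table: pd.DataFrame) -> pd.DataFrame:
    """Robust-scale every feature column: centre by median, scale by IQR.

    Zero-IQR columns are centred only.  Metadata columns (subject, label)
    pass through unchanged.
    """
    X, _, features = _split_table(table)
    scaled = RobustScaler().fit_transform(X.to_numpy(dtype=float))
    out = table.copy()
    out[features] = scaled
    return out


def select_features(
    table: pd.DataFrame,
    spec: SelectionSpec,
    seed: int | None = None,
    learner: BaseEstimator | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Fit the selection strategy on the whole table; return it reduced.

    For leakage-free evaluation use :func:`tune_and_evaluate`, which re-fits
    selection inside each training fold; this operation is for inspection and
    final-model reporting.
    """
    X, y, features = _split_table(table)
    selector = _make_selector(
        spec, seed, learner if learner is not None else ExtraTreesClassifier(random_state=seed)
    )
    selector.fit(X.to_numpy(dtype=float), y)
    mask = selector.get_support()
    selected = [f for f, keep in zip(features, mask) if keep]
    if not selected:
        raise ValueError("no features survive the selection")
    meta = [c for c in ("subject", "label") if c in table.columns]
    return table[meta + selected], selected


def _make_pipeline(model: ModelSpec, selection: SelectionSpec, seed: int | None):
    learner = model.make_learner(seed)
    return Pipeline(
        [
            ("scale", RobustScaler()),
            ("select", _make_selector(selection, seed, learner)),
            ("clf", learner),
        ]
    )


def tune_and_evaluate(
    table: pd.DataFrame,
    model: ModelSpec = ModelSpec(),
    selection: SelectionSpec = SelectionSpec(),
    folds: int = 10,
    seed: int = 0,
    inner_folds: int = 3,
) -> EvalResult:
    """Stratified k-fold evaluation of scale -> select -> learn.

    Scaling, selection and (when a grid is given) hyperparameter tuning are
    all fitted on each training fold only.  Reports the mean and SD of the
    fold accuracies in percent, the hyperparameters chosen on the full data,
    and the features selected on the full data.
    """
    X, y, features = _split_table(table)
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()
    counts = y.value_counts()
    if (counts < folds).any():
        small = counts[counts < folds].index.tolist()
        raise ValueError(
            f"classes {small} have fewer than {folds} members; "
            "reduce the fold count or stratify down"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accuracies = []
    for train, test in cv.split(Xv, yv):
        pipe = _make_pipeline(model, selection, seed)
        if model.grid:
            search = GridSearchCV(pipe, model.grid, cv=inner_folds, n_jobs=1)
            search.fit(Xv[train], yv[train])
            estimator = search.best_estimator_
        else:
            estimator = pipe.fit(Xv[train], yv[train])
        accuracies.append(100.0 * estimator.score(Xv[test], yv[test]))

    # final fit on all data for reporting chosen params and selected features
    final = _make_pipeline(model, selection, seed)
    if model.grid:
        search = GridSearchCV(final, model.grid, cv=inner_folds, n_jobs=1)
        search.fit(Xv, yv)
        chosen = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
        final = search.best_estimator_
    else:
        chosen = dict(model.params)
        final.fit(Xv, yv)
    mask = final.named_steps["select"].get_support()
    selected = [f for f, keep in zip(features, mask) if keep]

    return EvalResult(
        mean_accuracy=float(np.mean(accuracies)),
        accuracy_sd=float(np.std(accuracies, ddof=1)),
        fold_accuracies=[float(a) for a in accuracies],
        chosen_params=chosen,
        selected_features=selected,
    )
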