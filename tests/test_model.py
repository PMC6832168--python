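"""Scaling, feature selection and cross-validated ensemble evaluation."""

import numpy as np
import pandas as pd
import pytest

from ecgemotion import (
    ModelSpec,
    SelectionSpec,
    scale_features,
    select_features,
    tune_and_evaluate,
)

ETC_PARAMS = {"n_estimators": 71, "max_depth": 41, "max_features": 6}


def _synthetic_table(n_per_class=30, n_features=20, informative=3, seed=0,
                     separation=3.0):
    """Gaussian feature table with a few class-separated columns."""
    rng = np.random.default_rng(seed)
    classes = ["joy", "anger", "pleasure", "sadness"]
    rows = []
    for ci, cls in enumerate(classes):
        X = rng.normal(size=(n_per_class, n_features))
        X[:, :informative] += separation * ci
        for row in X:
            rows.append({"label": cls, **{f"f{j}": row[j] for j in range(n_features)}})
    return pd.DataFrame(rows)


class TestScaling:
    def test_median_removed_iqr_scaled(self):
        table = pd.DataFrame({"label": list("aabb"), "x": [1.0, 2.0, 3.0, 100.0]})
        out = scale_features(table)
        assert np.median(out["x"]) == pytest.approx(0.0)
        iqr = np.percentile([1, 2, 3, 100], 75) - np.percentile([1, 2, 3, 100], 25)
        assert np.allclose(out["x"], (np.array([1, 2, 3, 100]) - 2.5) / iqr)

    def test_constant_column_centred_only(self):
        table = pd.DataFrame({"label": list("aabb"), "x": [5.0] * 4})
        out = scale_features(table)
        assert np.allclose(out["x"], 0.0)

    def test_rescaling_keeps_median_zero(self):
        table = _synthetic_table(10)
        once = scale_features(table)
        twice = scale_features(once)
        feats = [c for c in table.columns if c != "label"]
        assert np.allclose(twice[feats].median(), 0.0, atol=1e-12)


class TestSelection:
    def test_none_keeps_everything(self):
        table = _synthetic_table(15)
        reduced, names = select_features(table, SelectionSpec("none"))
        assert len(names) == 20

    def test_rfe_returns_exact_count(self):
        table = _synthetic_table(15)
        _, names = select_features(
            table, SelectionSpec("rfe", n_features=10), seed=0
        )
        assert len(names) == 10

    def test_model_selection_finds_informative_column(self):
        # only column f0 carries class signal -> must be retained
        table = _synthetic_table(25, n_features=8, informative=1, seed=2)
        _, names = select_features(table, SelectionSpec("model_etc"), seed=0)
        assert "f0" in names

    def test_chi2_and_ptest_filter(self):
        table = scale_features(_synthetic_table(25, seed=3))
        _, chi_names = select_features(table, SelectionSpec("chi2", threshold=0.1))
        assert 0 < len(chi_names) <= 20
        _, p_names = select_features(table, SelectionSpec("ptest", threshold=0.01))
        assert set(p_names) >= {"f0", "f1", "f2"}

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SelectionSpec("rfe")
        with pytest.raises(ValueError):
            SelectionSpec("chi2")
        with pytest.raises(ValueError):
            SelectionSpec("not_a_method")


class TestEvaluation:
    def test_separable_data_high_accuracy(self):
        table = _synthetic_table(30, seed=4)
        res = tune_and_evaluate(
            table, ModelSpec("extra_trees", ETC_PARAMS),
            SelectionSpec("model_etc"), folds=10, seed=7,
        )
        assert res.mean_accuracy >= 90.0
        assert len(res.fold_accuracies) == 10
        assert res.selected_features

    def test_permuted_labels_at_chance(self):
        table = _synthetic_table(30, seed=5)
        rng = np.random.default_rng(11)
        table["label"] = rng.permutation(table["label"].to_numpy())
        res = tune_and_evaluate(
            table, ModelSpec("extra_trees", ETC_PARAMS),
            SelectionSpec("model_etc"), folds=10, seed=7,
        )
        assert 10.0 <= res.mean_accuracy <= 40.0  # chance is 25% for 4 classes

    def test_shuffled_never_beats_separable(self):
        table = _synthetic_table(15, seed=6)
        rng = np.random.default_rng(0)
        for seed in range(3):
            good = tune_and_evaluate(
                table, ModelSpec("random_forest", {"n_estimators": 30}),
                folds=5, seed=seed,
            )
            shuffled = table.copy()
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            bad = tune_and_evaluate(
                shuffled, ModelSpec("random_forest", {"n_estimators": 30}),
                folds=5, seed=seed,
            )
            assert good.mean_accuracy >= bad.mean_accuracy

    def test_reproducible_under_seed(self):
        table = _synthetic_table(15, seed=8)
        kwargs = dict(
            model=ModelSpec("extra_trees", {"n_estimators": 40}),
            selection=SelectionSpec("model_etc"),
            folds=5, seed=13,
        )
        a = tune_and_evaluate(table, **kwargs)
        b = tune_and_evaluate(table, **kwargs)
        assert a.fold_accuracies == b.fold_accuracies
        assert a.selected_features == b.selected_features

    def test_small_class_rejected(self):
        table = _synthetic_table(5)
        with pytest.raises(ValueError, match="fewer than 10"):
            tune_and_evaluate(table, folds=10)

    def test_grid_search_tunes_parameters(self):
        table = _synthetic_table(15, seed=9)
        res = tune_and_evaluate(
            table,
            ModelSpec("extra_trees", grid={"clf__n_estimators": [10, 30]}),
            folds=5, seed=1, inner_folds=2,
        )
        assert res.chosen_params["n_estimators"] in (10, 30)


@pytest.mark.parametrize("learner", ["gradient_boost", "adaboost_tree", "adaboost_nb"])
def test_other_learners_run(learner):
    table = _synthetic_table(12, n_features=6, seed=10)
    params = {"n_estimators": 10} if learner == "gradient_boost" else {}
    res = tune_and_evaluate(table, ModelSpec(learner, params), folds=4, seed=2)
    assert 0.0 <= res.mean_accuracy <= 100.0
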