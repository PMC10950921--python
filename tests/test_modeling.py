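import numpy as np
import pandas as pd
import pytest

from amlrec import (
    ModalityGridSearch,
    SplitSpec,
    TrainedModel,
    predict_outcome,
    select_best_per_modality,
    split_holdout,
    train_with_grid,
)
from amlrec.modeling import DEFAULT_GRIDS, encode_outcome


def _separable(n=80, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y == 1, 3.0, -3.0)  # wide margin
    return X, y


class TestSplitHoldout:
    def test_272_gives_paper_fold_sizes(self):
        split = split_holdout([f"P{i}" for i in range(272)], SplitSpec(seed=1))
        assert split.sizes["test"] == 28
        assert split.sizes["validation"] == 28
        assert split.sizes["train"] == 216  # feature-selection fold folded in
        assert len(split.feature_select_ids) == 28

    def test_n10_exact_tenths(self):
        split = split_holdout([f"P{i}" for i in range(10)], SplitSpec(seed=0))
        assert len(split.test_ids) == 1
        assert len(split.validation_ids) == 1
        assert len(split.feature_select_ids) == 1
        assert len(split.train_ids) == 7

    def test_deterministic_given_seed(self):
        ids = [f"P{i}" for i in range(95)]
        a = split_holdout(ids, SplitSpec(seed=5))
        b = split_holdout(ids, SplitSpec(seed=5))
        c = split_holdout(ids, SplitSpec(seed=6))
        assert a.test_ids == b.test_ids and a.train_ids == b.train_ids
        assert a.test_ids != c.test_ids

    @pytest.mark.parametrize("n,seed", [(10, 0), (37, 3), (100, 9), (273, 1)])
    def test_partitions_disjoint_and_exhaustive(self, n, seed):
        ids = [f"P{i}" for i in range(n)]
        split = split_holdout(ids, SplitSpec(seed=seed))
        folds = [split.train_ids, split.feature_select_ids,
                 split.validation_ids, split.test_ids]
        union = [i for fold in folds for i in fold]
        assert sorted(union) == sorted(ids)
        assert len(set(union)) == len(union)
        for fold in folds[1:]:
            assert len(fold) == int(np.ceil(0.1 * n))

    def test_merge_validation_into_train(self):
        ids = [f"P{i}" for i in range(272)]
        spec = SplitSpec(seed=1, merge_validation_into_train=True)
        split = split_holdout(ids, spec)
        assert split.sizes["train"] == 244  # the 9:1 ensemble stage

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            split_holdout([f"P{i}" for i in range(9)], SplitSpec(seed=0))


class TestGridSearch:
    def test_single_point_grid_returns_that_configuration(self):
        X, y = _separable()
        grid = {"n_estimators": [15], "max_depth": [8]}
        model = train_with_grid(
            "random_forest", grid, X[:60], y[:60], X[60:], y[60:],
            modality="clinical",
        )
        assert model.hyperparameters == {"n_estimators": 15, "max_depth": 8}
        assert model.estimator.n_grid_points_ == 1

    def test_grid_evaluation_count_is_product_of_candidates(self):
        X, y = _separable()
        grid = {"n_estimators": [10, 20], "min_samples_leaf": [1, 2, 3]}
        gs = ModalityGridSearch("random_forest", grid=grid).fit(
            X[:60], y[:60], X_val=X[60:], y_val=y[60:]
        )
        assert gs.n_grid_points_ == 6

    @pytest.mark.parametrize("method", ["random_forest", "logistic_regression", "svm"])
    def test_separable_data_reaches_perfect_validation_f1(self, method):
        X, y = _separable(n=120, seed=2)
        grid = {k: v[-2:] for k, v in DEFAULT_GRIDS[method].items()}
        model = train_with_grid(method, grid, X[:90], y[:90], X[90:], y[90:])
        assert model.validation_f1 == pytest.approx(1.0)

    def test_single_class_training_fold_rejected(self):
        X, y = _separable()
        with pytest.raises(ValueError, match="re-split"):
            ModalityGridSearch("random_forest", grid={"n_estimators": [5]}).fit(
                X[:30], np.zeros(30, dtype=int), X_val=X[60:], y_val=y[60:]
            )

    def test_winner_score_bounds_every_grid_point(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 5))
        y = rng.integers(0, 2, 100)
        from amlrec.evaluation import weighted_f1
        from amlrec.modeling import _base_estimator
        from sklearn.model_selection import ParameterGrid

        grid = {"n_estimators": [5, 10], "max_depth": [2, None]}
        gs = ModalityGridSearch("random_forest", grid=grid).fit(
            X[:70], y[:70], X_val=X[70:], y_val=y[70:]
        )
        for params in ParameterGrid(grid):
            est = _base_estimator("random_forest", params).fit(X[:70], y[:70])
            assert gs.validation_f1_ >= weighted_f1(y[70:], est.predict(X[70:])) - 1e-12


class TestPredictOutcome:
    def test_separable_positive_region_predicted_living(self):
        X, y = _separable(n=120, seed=3)
        model = train_with_grid(
            "logistic_regression", {"C": [10.0]}, X[:90], y[:90], X[90:], y[90:]
        )
        # class 0 (= living) lies at strongly negative first coordinate
        label, p_live = predict_outcome(model, np.array([-4.0, 0.0, 0.0]))
        assert label == "living" and p_live > 0.9

    def test_probability_always_in_unit_interval(self):
        X, y = _separable(n=100, seed=5)
        for method in ("random_forest", "svm"):
            grid = {k: v[:1] for k, v in DEFAULT_GRIDS[method].items()}
            model = train_with_grid(method, grid, X[:70], y[:70], X[70:], y[70:])
            p = model.estimator.predict_survive_proba(X)
            assert np.all((p >= 0) & (p <= 1))

    def test_exact_half_probability_labels_deceased(self):
        X, y = _separable()
        model = train_with_grid(
            "logistic_regression", {"C": [1.77e-1]}, X[:60], y[:60], X[60:], y[60:]
        )

        class Half:
            def predict_survive_proba(self, X):
                return np.array([0.5])

        model.estimator.predict_survive_proba = Half().predict_survive_proba
        label, p = predict_outcome(model, X[0])
        assert label == "deceased" and p == 0.5

    def test_missing_feature_rejected(self):
        X, y = _separable()
        model = train_with_grid(
            "logistic_regression", {"C": [10.0]}, X[:60], y[:60], X[60:], y[60:]
        )
        with pytest.raises(ValueError, match="missing"):
            predict_outcome(model, np.array([np.nan, 0.0, 0.0]))


def _stub(method, modality, f1):
    X, y = _separable(n=40, seed=1)
    est = ModalityGridSearch(method, grid={"C": [10.0]} if method != "random_forest"
                             else {"n_estimators": [5]})
    est.fit(X[:30], y[:30], X_val=X[30:], y_val=y[30:])
    est.validation_f1_ = f1
    return TrainedModel(method=method, modality=modality, estimator=est,
                        hyperparameters=est.best_params_, validation_f1=f1)


class TestBestPerModality:
    def test_published_pattern_best_expression_is_forest(self):
        models = [
            _stub("random_forest", "clinical", 0.6562),
            _stub("svm", "clinical", 0.6713),
            _stub("logistic_regression", "clinical", 0.7044),
            _stub("random_forest", "mutation", 0.7129),
            _stub("svm", "mutation", 0.4807),
            _stub("logistic_regression", "mutation", 0.7129),
            _stub("random_forest", "expression", 0.7803),
            _stub("svm", "expression", 0.6284),
            _stub("logistic_regression", "expression", 0.6200),
        ]
        best = select_best_per_modality(models)
        assert best["clinical"].method == "logistic_regression"
        assert best["expression"].method == "random_forest"
        assert best["expression"].validation_f1 == pytest.approx(0.7803)
        # exact F1 tie (mutation RF vs LR at 0.7129): forest wins by convention
        assert best["mutation"].method == "random_forest"

    def test_single_model_per_modality_is_identity(self):
        model = _stub("svm", "clinical", 0.5)
        assert select_best_per_modality([model])["clinical"] is model

    def test_outcome_encoding_positive_is_deceased(self):
        y = encode_outcome(["living", "deceased", "living"])
        assert y.tolist() == [0, 1, 0]
        with pytest.raises(ValueError, match="unknown"):
            encode_outcome(["alive"])
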