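"""Hold-out partitioning and per-modality classifier training.

Each of three classifier families (random forest, logistic regression, SVM)
is fitted per modality with an exhaustive grid search scored by weighted F1
on a dedicated validation fold.  The deceased class is the positive class
throughout; internally labels are encoded 1 = deceased, 0 = living.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .cohort import (
    ELN_CATEGORIES,
    GENDER_CATEGORIES,
    NUMERIC_CLINICAL,
    Cohort,
    Protocol,
)
from .evaluation import weighted_f1

__all__ = [
    "METHODS",
    "MODALITIES",
    "DEFAULT_GRIDS",
    "COMPACT_GRIDS",
    "SplitSpec",
    "HoldoutSplit",
    "split_holdout",
    "ModalityEncoder",
    "ModalityGridSearch",
    "TrainedModel",
    "train_with_grid",
    "predict_outcome",
    "select_best_per_modality",
    "encode_outcome",
]

#: Canonical method order; also the tie-break order for best-per-modality.
METHODS: tuple[str, ...] = ("random_forest", "logistic_regression", "svm")
MODALITIES: tuple[str, ...] = ("clinical", "mutation", "expression")

#: Grid-search candidate values per method; everything else stays at library
#: defaults.  Logistic regression and SVM carry a fixed random_state=1.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [10, 15, 20, 25, 30, 45, 50],
        "min_samples_leaf": [1, 2, 3, 4],
        "max_depth": [8, 10, None],
        "class_weight": ["balanced", None],
    },
    "logistic_regression": {
        "C": [1e-6, 5.62e-5, 3.166e-3, 1.77e-1, 10.0],
        "class_weight": ["balanced", None],
        "penalty": ["l2"],
    },
    "svm": {
        "kernel": ["linear", "rbf"],
        "C": [1e-6, 1e-5, 1e-4, 1e-3, 1e-2],
        "class_weight": ["balanced", None],
    },
}

#: Reduced grids for simulation studies where the full grid's cost dominates.
COMPACT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [25, 50],
        "min_samples_leaf": [1, 3],
        "max_depth": [None],
        "class_weight": ["balanced", None],
    },
    "logistic_regression": {
        "C": [3.166e-3, 1.77e-1, 10.0],
        "class_weight": ["balanced", None],
        "penalty": ["l2"],
    },
    "svm": {
        "kernel": ["linear", "rbf"],
        "C": [1e-4, 1e-2],
        "class_weight": ["balanced", None],
    },
}


def encode_outcome(status: Sequence[object]) -> np.ndarray:
    """Encode survival labels: 1 = deceased (positive class), 0 = living."""
    s = pd.Series(status)
    unknown = s.dropna()[~s.dropna().isin(["living", "deceased"])]
    if len(unknown):
        raise ValueError(f"unknown survival labels: {sorted(set(unknown))}")
    return (s == "deceased").astype(int).to_numpy()


# ---------------------------------------------------------------------------
# hold-out split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """70/10/10/10 hold-out: train / feature-selection / validation / test.

    Held-out fold sizes are ceiling(fraction * n); training takes the
    remainder.  With ``merge_feature_select_into_train`` (default) the
    feature-selection fold rejoins the model-training set after selection,
    so at n = 272 the effective training set is 216 with 28/28 validation
    and test.  ``merge_validation_into_train`` is the ensemble-stage 9:1
    refit switch.
    """

    fractions: tuple[float, float, float, float] = (0.7, 0.1, 0.1, 0.1)
    seed: int = 0
    merge_feature_select_into_train: bool = True
    merge_validation_into_train: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class HoldoutSplit:
    train_ids: list
    feature_select_ids: list
    validation_ids: list
    test_ids: list
    spec: SplitSpec

    @property
    def model_train_ids(self) -> list:
        """Ids used to fit the individual models, after fold merging."""
        ids = list(self.train_ids)
        if self.spec.merge_feature_select_into_train:
            ids += list(self.feature_select_ids)
        if self.spec.merge_validation_into_train:
            ids += list(self.validation_ids)
        return ids

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "train": len(self.model_train_ids),
            "feature_select": len(self.feature_select_ids),
            "validation": len(self.validation_ids),
            "test": len(self.test_ids),
        }


def split_holdout(cohort_or_ids, spec: SplitSpec) -> HoldoutSplit:
    """Partition patient ids into the four disjoint hold-out folds."""
    if isinstance(cohort_or_ids, Cohort):
        ids = np.asarray(cohort_or_ids.patient_ids, dtype=object)
    else:
        ids = np.asarray(list(cohort_or_ids), dtype=object)
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    _, f_fs, f_val, f_test = spec.fractions
    n_fs = math.ceil(f_fs * n)
    n_val = math.ceil(f_val * n)
    n_test = math.ceil(f_test * n)
    n_train = n - n_fs - n_val - n_test
    if n_train <= 0:
        raise ValueError(f"n={n} too small for non-empty training fold")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    test = ids[perm[:n_test]]
    val = ids[perm[n_test:n_test + n_val]]
    fs = ids[perm[n_test + n_val:n_test + n_val + n_fs]]
    train = ids[perm[n_test + n_val + n_fs:]]
    return HoldoutSplit(
        train_ids=list(train),
        feature_select_ids=list(fs),
        validation_ids=list(val),
        test_ids=list(test),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class ModalityEncoder:
    """Turns cohort tables into numeric per-modality design matrices.

    Clinical categoricals are one-hot encoded against fixed category lists
    (captured at fit) so a counterfactual sweep over treatment intensity
    always sees all four protocol columns.  Genetic tables pass through
    restricted to their selected panels.
    """

    clinical_features: list[str]
    mutation_features: list[str]
    expression_features: list[str]
    categories: dict[str, tuple[str, ...]] = field(default_factory=dict)

    FIXED_CATEGORIES = {
        "gender": GENDER_CATEGORIES,
        "eln_risk": ELN_CATEGORIES,
        "treatment_intensity": Protocol.labels(),
    }

    @classmethod
    def fit(
        cls,
        cohort: Cohort,
        clinical_features: Sequence[str],
        mutation_features: Sequence[str],
        expression_features: Sequence[str],
    ) -> "ModalityEncoder":
        predictors = [
            f for f in clinical_features if f != "overall_survival_status"
        ]
        categories: dict[str, tuple[str, ...]] = {}
        for col in predictors:
            if col in NUMERIC_CLINICAL or col == "is_white":
                continue
            if col in cls.FIXED_CATEGORIES:
                categories[col] = tuple(cls.FIXED_CATEGORIES[col])
            else:
                observed = cohort.clinical[col].dropna().unique()
                categories[col] = tuple(sorted(str(v) for v in observed))
        return cls(
            clinical_features=predictors,
            mutation_features=list(mutation_features),
            expression_features=list(expression_features),
            categories=categories,
        )

    def clinical_matrix(self, clinical: pd.DataFrame) -> pd.DataFrame:
        parts = []
        for col in self.clinical_features:
            if col in self.categories:
                cats = self.categories[col]
                values = clinical[col].astype(object)
                for cat in cats:
                    parts.append(
                        (values == cat).astype(float).rename(f"{col}={cat}")
                    )
            else:
                parts.append(
                    pd.to_numeric(clinical[col], errors="raise")
                    .astype(float).rename(col)
                )
        return pd.concat(parts, axis=1)

    def matrix(self, modality: str, cohort: Cohort) -> pd.DataFrame:
        if modality == "clinical":
            return self.clinical_matrix(cohort.clinical)
        if modality == "mutation":
            return cohort.mutations[self.mutation_features].astype(float)
        if modality == "expression":
            return cohort.expression[self.expression_features].astype(float)
        raise KeyError(modality)


# ---------------------------------------------------------------------------
# grid-searched modality classifier
# ---------------------------------------------------------------------------

def _base_estimator(method: str, params: Mapping) -> Pipeline:
    params = dict(params)
    if method == "random_forest":
        clf = RandomForestClassifier(random_state=1, **params)
        steps = [("clf", clf)]
    elif method == "logistic_regression":
        penalty = params.pop("penalty", "l2")
        if penalty != "l2":  # ridge is the only penalty in the search space
            raise ValueError(f"unsupported penalty {penalty!r}")
        clf = LogisticRegression(random_state=1, max_iter=5000, **params)
        steps = [("scale", StandardScaler()), ("clf", clf)]
    elif method == "svm":
        clf = SVC(random_state=1, **params)
        steps = [("scale", StandardScaler()), ("clf", clf)]
    else:
        raise ValueError(f"unknown method {method!r}")
    return Pipeline(steps)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class ModalityGridSearch(BaseEstimator, ClassifierMixin):
    """Exhaustive grid search for one classifier family on one modality.

    ``fit`` takes explicit validation data (hold-out protocol, not
    cross-validation); every grid point is fitted on the training data and
    scored on the validation fold by weighted F1.  Ties keep the earlier grid
    point.  SVMs expose no probabilities, so a logistic link is fitted on the
    validation decision scores to produce a probability-like survival score.

    Attributes
    ----------
    best_params_ : winning hyperparameters.
    best_estimator_ : the winning fitted pipeline.
    validation_f1_ : weighted F1 of the winner on the validation fold.
    n_grid_points_ : number of configurations evaluated.
    """

    def __init__(self, method: str = "random_forest", modality: str | None = None,
                 grid: Mapping[str, list] | None = None,
                 objective: str = "f1_weighted"):
        self.method = method
        self.modality = modality
        self.grid = grid
        self.objective = objective

    def fit(self, X, y, X_val=None, y_val=None):
        if X_val is None or y_val is None:
            raise ValueError("hold-out grid search requires X_val and y_val")
        if self.objective != "f1_weighted":
            raise ValueError("only the weighted-F1 objective is supported")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError(
                "training fold contains a single class; re-split with a "
                "different seed"
            )
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.method]
        if any(len(v) == 0 for v in grid.values()):
            raise ValueError("grid candidate lists must be non-empty")
        best_score, best_params, best_est = -np.inf, None, None
        n_points = 0
        for params in ParameterGrid(dict(grid)):
            n_points += 1
            est = _base_estimator(self.method, params).fit(X, y)
            score = weighted_f1(y_val, est.predict(X_val))
            if score > best_score:
                best_score, best_params, best_est = score, params, est
        self.n_grid_points_ = n_points
        self.best_params_ = best_params
        self.best_estimator_ = best_est
        self.validation_f1_ = float(best_score)
        self.classes_ = np.array([0, 1])
        self._fit_calibrator(X_val, y_val)
        return self

    def _fit_calibrator(self, X_val, y_val):
        """Logistic link on decision scores for margin-only classifiers."""
        self.calibrator_ = None
        if self.method != "svm":
            return
        scores = self.best_estimator_.decision_function(X_val).reshape(-1, 1)
        if len(np.unique(y_val)) == 2 and len(np.unique(scores)) > 1:
            self.calibrator_ = LogisticRegression(random_state=1).fit(
                scores, y_val
            )

    def refit_best(self, X, y):
        """Refit the winning configuration on new data (e.g. train+validation
        for the ensemble stage); the recorded validation F1 is kept."""
        check_is_fitted(self, "best_params_")
        self.best_estimator_ = _base_estimator(self.method, self.best_params_).fit(
            np.asarray(X, dtype=float), np.asarray(y, dtype=int)
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(np.asarray(X, dtype=float))

    def predict_survive_proba(self, X) -> np.ndarray:
        """Probability-like score for the living class (1 - P(deceased))."""
        check_is_fitted(self, "best_estimator_")
        X = np.asarray(X, dtype=float)
        if self.method == "svm":
            scores = self.best_estimator_.decision_function(X)
            if self.calibrator_ is not None:
                p_dec = self.calibrator_.predict_proba(scores.reshape(-1, 1))[:, 1]
            else:
                p_dec = _sigmoid(scores)
            return 1.0 - p_dec
        proba = self.best_estimator_.predict_proba(X)
        classes = list(self.best_estimator_.classes_)
        if 0 in classes:
            return proba[:, classes.index(0)]
        return 1.0 - proba[:, classes.index(1)]


@dataclass
class TrainedModel:
    """A fitted per-modality classifier with its validation F1."""

    method: str
    modality: str
    estimator: ModalityGridSearch
    hyperparameters: dict
    validation_f1: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.validation_f1 <= 1.0):
            raise ValueError("validation_f1 must lie in [0, 1]")


def train_with_grid(
    method: str,
    grid: Mapping[str, list] | None,
    X_train, y_train, X_val, y_val,
    modality: str = "unknown",
    objective: str = "f1_weighted",
) -> TrainedModel:
    """Grid-search one method on one modality; returns the fitted winner."""
    gs = ModalityGridSearch(
        method=method, modality=modality, grid=grid, objective=objective
    ).fit(X_train, y_train, X_val=X_val, y_val=y_val)
    return TrainedModel(
        method=method,
        modality=modality,
        estimator=gs,
        hyperparameters=dict(gs.best_params_),
        validation_f1=gs.validation_f1_,
    )


def predict_outcome(model: TrainedModel, X_row) -> tuple[str, float]:
    """Predict one record: (label, survive probability).

    The label follows the arg-max class; at survive probability exactly 0.5
    the fixed convention is deceased (the clinically conservative call).
    """
    X = np.asarray(X_row, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if np.isnan(X).any():
        j = int(np.flatnonzero(np.isnan(X).any(axis=0))[0])
        raise ValueError(f"missing feature value at column index {j}")
    p_live = float(model.estimator.predict_survive_proba(X)[0])
    label = "living" if p_live > 0.5 else "deceased"
    return label, p_live


def select_best_per_modality(
    models: Sequence[TrainedModel],
) -> dict[str, TrainedModel]:
    """Best validation-F1 model per modality; ties keep the earliest method
    in canonical order (RF, LR, SVM)."""
    if not models:
        raise ValueError("no models given")
    best: dict[str, TrainedModel] = {}
    order = {m: i for i, m in enumerate(METHODS)}
    for modality in sorted({m.modality for m in models}):
        cands = [m for m in models if m.modality == modality]
        cands.sort(key=lambda m: (-m.validation_f1, order.get(m.method, 99)))
        best[modality] = cands[0]
    return best
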