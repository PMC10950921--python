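"""Per-modality feature selection.

Three routes, one per modality:

* clinical — an expert-curated list (the 11-feature panel) intersected with
  the candidate schema;
* expression — L1-penalized linear SVM (squared hinge) at fixed C on
  standardized columns, keeping features with non-zero coefficients;
* mutation — per-gene 2x2 chi-square tests of mutation x outcome
  independence, keeping genes with p below a threshold (default 0.1, strict,
  no multiple-testing correction).

The expression and mutation selectors are scikit-learn style transformers;
``select_*`` functions are thin wrappers returning a :class:`SelectionResult`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .cohort import CLINICAL_FEATURES

__all__ = [
    "SelectionResult",
    "Chi2Result",
    "chi2_independence",
    "select_clinical_expert",
    "select_expression_l1",
    "select_mutations_chi2",
    "L1ExpressionSelector",
    "Chi2MutationSelector",
    "EXPERT_CLINICAL_PANEL",
]

#: Default expert panel: the 11 curated clinical features (the last is the
#: survival class label).
EXPERT_CLINICAL_PANEL: tuple[str, ...] = CLINICAL_FEATURES


@dataclass
class SelectionResult:
    modality: str
    selected: list[str]
    scores: dict[str, float]
    threshold: float | None


def select_clinical_expert(
    candidates: Sequence[str],
    expert_list: Sequence[str] | None = None,
) -> SelectionResult:
    """Return the expert-listed clinical features, in expert-list order."""
    expert_list = list(expert_list if expert_list is not None else EXPERT_CLINICAL_PANEL)
    cand = set(candidates)
    missing = [f for f in expert_list if f not in cand]
    if missing:
        raise KeyError(f"expert features absent from candidates: {missing}")
    return SelectionResult(
        modality="clinical",
        selected=list(expert_list),
        scores={f: 1.0 for f in expert_list},
        threshold=None,
    )


class Chi2Result(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def chi2_independence(table: np.ndarray | Sequence[Sequence[float]]) -> Chi2Result:
    """Pearson chi-square test of independence on a 2x2 table.

    No continuity correction, df = 1, upper-tail p-value.  A zero row or
    column marginal makes the statistic undefined; by convention the result
    is then (0, 1) with the ``degenerate`` flag set.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if (rows == 0).any() or (cols == 0).any():
        return Chi2Result(0.0, 1.0, degenerate=True)
    expected = np.outer(rows, cols) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return Chi2Result(stat, p, degenerate=False)


class L1ExpressionSelector(BaseEstimator, TransformerMixin):
    """Select expression features via an L1-penalized linear SVM.

    Columns are standardized (mean 0, sd 1) before the fit because the L1
    penalty is scale-sensitive; zero-variance columns are excluded (they carry
    no information and break standardization) and recorded in ``notices_``.

    Parameters
    ----------
    C : inverse regularization strength; smaller means sparser.
    tol, max_iter, random_state : passed to the liblinear solver.

    Attributes
    ----------
    selected_features_ : features with non-zero coefficient, input order.
    scores_ : mapping feature -> \\|coefficient\\|, for every candidate kept.
    """

    def __init__(self, C: float = 0.01, tol: float = 1e-4,
                 max_iter: int = 10_000, random_state: int = 1):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(np.unique(y[~pd.isna(y)])) < 2:
            raise ValueError("y must contain two classes")
        if pd.isna(X.to_numpy(dtype=float)).any():
            raise ValueError("X must not contain missing values")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        variances = X.to_numpy(dtype=float).var(axis=0)
        keep = variances > 0
        self.notices_ = []
        if not keep.all():
            dropped = [str(c) for c in X.columns[~keep]]
            self.notices_.append(f"excluded zero-variance columns: {dropped}")
        cols = X.columns[keep]
        Z = StandardScaler().fit_transform(X[cols].to_numpy(dtype=float))
        svc = LinearSVC(
            penalty="l1", loss="squared_hinge", dual=False, C=self.C,
            tol=self.tol, max_iter=self.max_iter, random_state=self.random_state,
        )
        svc.fit(Z, y)
        coef = np.abs(svc.coef_.ravel())
        self.scores_ = {str(c): float(v) for c, v in zip(cols, coef)}
        self.selected_features_ = [str(c) for c, v in zip(cols, coef) if v > 0]
        self.support_ = np.array(
            [str(c) in set(self.selected_features_) for c in X.columns]
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        return pd.DataFrame(X)[self.selected_features_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


class Chi2MutationSelector(BaseEstimator, TransformerMixin):
    """Select mutation features by per-gene chi-square independence tests.

    One 2x2 mutation-by-outcome table per gene; genes with upper-tail p
    strictly below ``alpha`` are kept, with no multiple-testing correction.

    Attributes
    ----------
    selected_features_ : genes with p < alpha, input order.
    pvalues_, statistics_ : mapping gene -> test result.
    """

    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def fit(self, X, y):
        if not (0 <= self.alpha < 1):
            raise ValueError("alpha must be in [0, 1)")
        X = pd.DataFrame(X)
        M = X.to_numpy(dtype=float)
        if not np.isin(M[~np.isnan(M)], (0.0, 1.0)).all():
            raise ValueError("mutation matrix must be binary")
        y = np.asarray(y).astype(int)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.pvalues_ = {}
        self.statistics_ = {}
        self.selected_features_ = []
        for j, gene in enumerate(X.columns):
            m = M[:, j]
            table = np.array([
                [np.sum((m == 0) & (y == 0)), np.sum((m == 0) & (y == 1))],
                [np.sum((m == 1) & (y == 0)), np.sum((m == 1) & (y == 1))],
            ])
            res = chi2_independence(table)
            self.pvalues_[str(gene)] = res.pvalue
            self.statistics_[str(gene)] = res.statistic
            if res.pvalue < self.alpha:
                self.selected_features_.append(str(gene))
        self.support_ = np.array(
            [str(c) in set(self.selected_features_) for c in X.columns]
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        return pd.DataFrame(X)[self.selected_features_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


def select_expression_l1(
    X: pd.DataFrame,
    y: Sequence[int],
    C: float = 0.01,
    **kwargs,
) -> SelectionResult:
    """L1 selection on a patients-by-genes expression matrix."""
    sel = L1ExpressionSelector(C=C, **kwargs).fit(X, y)
    return SelectionResult(
        modality="expression",
        selected=list(sel.selected_features_),
        scores=dict(sel.scores_),
        threshold=C,
    )


def select_mutations_chi2(
    M: pd.DataFrame,
    y: Sequence[int],
    alpha: float = 0.1,
) -> SelectionResult:
    """Chi-square selection on a patients-by-genes binary mutation matrix."""
    sel = Chi2MutationSelector(alpha=alpha).fit(M, y)
    return SelectionResult(
        modality="mutation",
        selected=list(sel.selected_features_),
        scores=dict(sel.pvalues_),
        threshold=alpha,
    )
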