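"""End-to-end orchestration: split, select features, train nine models,
build the weighted-vote committee, evaluate, recommend.

This is the programmatic equivalent of the full decision-support workflow:
hold-out partitioning, per-modality feature selection on the dedicated fold,
a 3-method x 3-modality grid search scored on the validation fold,
best-per-modality committee construction with F1-derived vote weights, a 9:1
refit of the members (validation folded back into training), test-set
evaluation of members and committee, and the counterfactual protocol
recommendation for the test patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort
from .ensemble import (
    DEFAULT_WEIGHT_CAP,
    Committee,
    build_committee,
    committee_predict_cohort,
)
from .evaluation import MetricsReport, evaluate_predictions
from .features import (
    SelectionResult,
    select_clinical_expert,
    select_expression_l1,
    select_mutations_chi2,
)
from .modeling import (
    DEFAULT_GRIDS,
    METHODS,
    ModalityEncoder,
    SplitSpec,
    TrainedModel,
    encode_outcome,
    split_holdout,
    train_with_grid,
)
from .recommend import Recommendation, RecommendationSummary, recommend_cohort

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    split: object
    selections: dict[str, SelectionResult]
    models: list[TrainedModel]
    committee: Committee
    individual_test_metrics: dict[str, MetricsReport]
    ensemble_test_metrics: MetricsReport
    recommendations: list[Recommendation]
    recommendation_summary: RecommendationSummary
    notes: list = field(default_factory=list)


def _expression_selection(X, y, C: float, notes: list) -> SelectionResult:
    """L1 expression selection with an escalating-penalty fallback.

    On small feature-selection folds the fixed C can shrink every
    coefficient to zero; the pipeline then relaxes the penalty tenfold at a
    time (up to C = 10) until at least one feature survives, and logs the C
    actually used.
    """
    c = C
    while True:
        selection = select_expression_l1(X, y, C=c)
        if selection.selected or c >= 10:
            break
        c *= 10
    if c != C:
        notes.append(
            f"expression: selection empty at C={C}; relaxed penalty to C={c} "
            f"({len(selection.selected)} features)"
        )
    return selection


def _mutation_selection(M, y, alpha: float, notes: list) -> SelectionResult:
    """Chi-square mutation selection, falling back to the single smallest-p
    gene when no gene clears the threshold on a small fold."""
    selection = select_mutations_chi2(M, y, alpha=alpha)
    if not selection.selected and selection.scores:
        best = min(selection.scores, key=selection.scores.get)
        notes.append(
            f"mutation: no gene with p < {alpha}; kept smallest-p gene {best}"
        )
        selection = SelectionResult(
            modality=selection.modality, selected=[best],
            scores=selection.scores, threshold=selection.threshold,
        )
    return selection


def run_pipeline(
    cohort: Cohort,
    seed: int = 0,
    *,
    methods: Sequence[str] = METHODS,
    grids: Mapping[str, Mapping[str, list]] | None = None,
    expression_C: float = 0.01,
    mutation_alpha: float = 0.1,
    weight_cap: int = DEFAULT_WEIGHT_CAP,
    feature_select_on_fold: bool = True,
    min_margin: float = 0.0,
) -> PipelineResult:
    """Run the full workflow on a preprocessed cohort."""
    grids = grids or DEFAULT_GRIDS
    notes: list[str] = []

    split = split_holdout(cohort, SplitSpec(seed=seed))
    fs_ids = (
        split.feature_select_ids if feature_select_on_fold else cohort.patient_ids
    )
    fs_cohort = cohort.subset(fs_ids)
    y_fs = encode_outcome(fs_cohort.clinical["overall_survival_status"])

    clin_sel = select_clinical_expert(list(cohort.clinical.columns))
    exp_sel = _expression_selection(
        fs_cohort.expression, y_fs, C=expression_C, notes=notes
    )
    mut_sel = _mutation_selection(
        fs_cohort.mutations, y_fs, alpha=mutation_alpha, notes=notes
    )
    selections = {
        "clinical": clin_sel, "expression": exp_sel, "mutation": mut_sel,
    }

    encoder = ModalityEncoder.fit(
        cohort,
        clinical_features=clin_sel.selected,
        mutation_features=mut_sel.selected,
        expression_features=exp_sel.selected,
    )

    train_cohort = cohort.subset(split.model_train_ids)
    val_cohort = cohort.subset(split.validation_ids)
    test_cohort = cohort.subset(split.test_ids)
    y_train = encode_outcome(train_cohort.clinical["overall_survival_status"])
    y_val = encode_outcome(val_cohort.clinical["overall_survival_status"])
    y_test_labels = test_cohort.clinical["overall_survival_status"]

    models: list[TrainedModel] = []
    for modality in ("clinical", "mutation", "expression"):
        X_train = encoder.matrix(modality, train_cohort)
        X_val = encoder.matrix(modality, val_cohort)
        for method in methods:
            models.append(train_with_grid(
                method, grids[method], X_train, y_train, X_val, y_val,
                modality=modality,
            ))

    committee = build_committee(models, encoder, cap=weight_cap)

    # 9:1 stage: members refit with the validation fold folded into training
    refit_ids = split.model_train_ids + list(split.validation_ids)
    refit_cohort = cohort.subset(refit_ids)
    y_refit = encode_outcome(refit_cohort.clinical["overall_survival_status"])
    for modality, model in committee.members.items():
        model.estimator.refit_best(
            encoder.matrix(modality, refit_cohort), y_refit
        )

    individual_test_metrics = {}
    for modality, model in committee.members.items():
        X_test = encoder.matrix(modality, test_cohort)
        pred = model.estimator.predict(X_test)
        p_live = model.estimator.predict_survive_proba(X_test)
        labels = np.where(pred == 1, "deceased", "living")
        individual_test_metrics[modality] = evaluate_predictions(
            y_test_labels, labels, survive_scores=p_live
        )

    committee_frame = committee_predict_cohort(committee, test_cohort)
    ensemble_test_metrics = evaluate_predictions(
        y_test_labels,
        committee_frame["label"],
        survive_scores=committee_frame["survive_score"],
    )

    recommendations, summary = recommend_cohort(
        committee, test_cohort, min_margin=min_margin
    )
    return PipelineResult(
        split=split,
        selections=selections,
        models=models,
        committee=committee,
        individual_test_metrics=individual_test_metrics,
        ensemble_test_metrics=ensemble_test_metrics,
        recommendations=recommendations,
        recommendation_summary=summary,
        notes=notes,
    )
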