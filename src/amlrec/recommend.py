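"""Counterfactual treatment-intensity recommendation.

For each patient, the committee is re-applied four times with the
treatment-intensity feature set to each protocol in turn while every other
feature is held fixed; the recommended protocol is the one with the highest
committee survival score.  Genetic members do not see treatment intensity, so
their contribution is constant across the sweep by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, Protocol
from .ensemble import Committee, committee_predict_cohort

__all__ = [
    "Recommendation",
    "RecommendationSummary",
    "sweep_protocols",
    "sweep_protocols_cohort",
    "recommend_protocol",
    "recommend_cohort",
]


@dataclass
class Recommendation:
    patient_id: str
    scores: dict[Protocol, float]
    recommended: Protocol
    margin: float
    tie: bool = False
    low_confidence: bool = False


@dataclass
class RecommendationSummary:
    distribution: dict[Protocol, int]
    mean_margin: float
    n: int
    errors: dict = field(default_factory=dict)


def sweep_protocols_cohort(committee: Committee, cohort: Cohort) -> pd.DataFrame:
    """Survival score under each protocol, for every patient at once.

    Returns a patients x protocols frame of committee survival scores.
    """
    cols = {}
    for protocol in Protocol.canonical_order():
        counterfactual = cohort.copy()
        counterfactual.clinical = counterfactual.clinical.copy()
        counterfactual.clinical["treatment_intensity"] = protocol.value
        frame = committee_predict_cohort(committee, counterfactual)
        cols[protocol.value] = frame["survive_score"]
    return pd.DataFrame(cols, index=cohort.clinical.index)


def sweep_protocols(
    committee: Committee, cohort: Cohort, patient_id=None
) -> dict[Protocol, float]:
    """One patient's survival score under each of the four protocols."""
    if patient_id is None:
        if cohort.n_patients != 1:
            raise ValueError("give patient_id for multi-record cohorts")
        patient_id = cohort.patient_ids[0]
    sweep = sweep_protocols_cohort(committee, cohort.subset([patient_id]))
    row = sweep.iloc[0]
    return {p: float(row[p.value]) for p in Protocol.canonical_order()}


def _pick(scores: dict[Protocol, float]) -> tuple[Protocol, float, bool]:
    best = max(scores.values())
    winners = [p for p in Protocol.canonical_order() if scores[p] == best]
    recommended = winners[0]  # canonical order: less burdensome first
    others = [v for p, v in scores.items() if p is not recommended]
    margin = best - max(others) if others else 0.0
    return recommended, margin, len(winners) > 1


def recommend_protocol(
    committee: Committee,
    cohort: Cohort,
    patient_id=None,
    min_margin: float = 0.0,
) -> Recommendation:
    """Recommend the survival-maximizing protocol for one patient.

    Exact score ties resolve to the earliest protocol in canonical order
    (the clinically conservative, less burdensome default) and are flagged.
    A margin below ``min_margin`` raises the low-confidence flag.
    """
    if patient_id is None:
        if cohort.n_patients != 1:
            raise ValueError("give patient_id for multi-record cohorts")
        patient_id = cohort.patient_ids[0]
    scores = sweep_protocols(committee, cohort, patient_id)
    recommended, margin, tie = _pick(scores)
    return Recommendation(
        patient_id=str(patient_id),
        scores=scores,
        recommended=recommended,
        margin=margin,
        tie=tie,
        low_confidence=margin < min_margin,
    )


def recommend_cohort(
    committee: Committee,
    cohort: Cohort,
    min_margin: float = 0.0,
) -> tuple[list[Recommendation], RecommendationSummary]:
    """Per-patient recommendations plus an aggregate summary.

    Per-record failures are collected in the summary rather than aborting
    the batch.
    """
    recommendations: list[Recommendation] = []
    errors: dict[str, str] = {}
    if cohort.n_patients:
        try:
            sweep = sweep_protocols_cohort(committee, cohort)
        except ValueError:
            sweep = None
        for pid in cohort.patient_ids:
            try:
                if sweep is not None:
                    row = sweep.loc[pid]
                    scores = {
                        p: float(row[p.value]) for p in Protocol.canonical_order()
                    }
                else:
                    scores = sweep_protocols(committee, cohort, pid)
                recommended, margin, tie = _pick(scores)
                recommendations.append(Recommendation(
                    patient_id=str(pid), scores=scores, recommended=recommended,
                    margin=margin, tie=tie, low_confidence=margin < min_margin,
                ))
            except ValueError as exc:
                errors[str(pid)] = str(exc)
    distribution = {p: 0 for p in Protocol.canonical_order()}
    for rec in recommendations:
        distribution[rec.recommended] += 1
    mean_margin = (
        float(np.mean([r.margin for r in recommendations]))
        if recommendations else 0.0
    )
    summary = RecommendationSummary(
        distribution=distribution,
        mean_margin=mean_margin,
        n=len(recommendations),
        errors=errors,
    )
    return recommendations, summary
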