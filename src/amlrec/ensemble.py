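"""F1-weighted voting committee over the best per-modality classifiers.

Each member's ballot size is an integer computed from its validation F1:

    vote(M) = ceil( 1 / log10(1 / F1) )

The weight grows without bound as F1 approaches 1, so a configurable cap
(default 100) keeps votes finite; F1 = 0 silences the member.  The committee
label is the class with the larger summed ballot; the committee's survival
score is the vote-weighted mean of the members' survival probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .modeling import (
    METHODS,
    ModalityEncoder,
    TrainedModel,
    select_best_per_modality,
)

__all__ = [
    "DEFAULT_WEIGHT_CAP",
    "vote_weight",
    "Committee",
    "build_committee",
    "committee_predict",
    "committee_predict_cohort",
]

DEFAULT_WEIGHT_CAP = 100

#: Snap tolerance: the formula is evaluated to an integer before ceiling when
#: within this distance, so exact powers of ten (F1 = 0.1 -> weight 1) do not
#: drift to ceil(x + eps).
_SNAP_TOL = 1e-12


def vote_weight(f1: float, cap: int = DEFAULT_WEIGHT_CAP) -> int:
    """Integer ballot size from a validation F1 score.

    Non-decreasing in F1 on (0, 1); 0 at F1 = 0 (no evidence) and ``cap`` at
    F1 = 1, where the formula is singular.
    """
    if not (0.0 <= f1 <= 1.0):
        raise ValueError(f"f1 must lie in [0, 1], got {f1}")
    if f1 == 0.0:
        return 0
    if f1 == 1.0:
        return cap
    x = 1.0 / -math.log10(f1)  # == 1 / log10(1/f1)
    nearest = round(x)
    if abs(x - nearest) <= _SNAP_TOL:
        w = int(nearest)
    else:
        w = int(math.ceil(x))
    return min(w, cap)


@dataclass
class Committee:
    """Best-per-modality members plus their integer vote weights."""

    members: dict[str, TrainedModel]
    weights: dict[str, int]
    encoder: ModalityEncoder
    weight_cap: int = DEFAULT_WEIGHT_CAP

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("committee needs at least one member")
        if set(self.members) != set(self.weights):
            raise ValueError("members and weights must cover the same modalities")

    @property
    def modalities(self) -> list[str]:
        return sorted(self.members)


def build_committee(
    models: Sequence[TrainedModel],
    encoder: ModalityEncoder,
    cap: int = DEFAULT_WEIGHT_CAP,
) -> Committee:
    """Select the best model per modality and weight each by its F1 ballot."""
    best = select_best_per_modality(models)
    weights = {
        modality: vote_weight(model.validation_f1, cap)
        for modality, model in best.items()
    }
    if all(w == 0 for w in weights.values()):
        raise ValueError("all vote weights are zero; committee is mute")
    return Committee(members=best, weights=weights, encoder=encoder, weight_cap=cap)


def committee_predict_cohort(
    committee: Committee, cohort: Cohort
) -> pd.DataFrame:
    """Vectorized committee prediction for every patient in a cohort.

    Returns a frame indexed by patient id with the committee label, the
    vote-weighted survival score, the per-class vote sums and per-member
    labels.  Weight-sum ties fall back to the survival score against 0.5;
    a score of exactly 0.5 resolves to deceased (fixed convention).
    """
    n = cohort.n_patients
    votes_living = np.zeros(n)
    votes_deceased = np.zeros(n)
    weighted_p = np.zeros(n)
    total_w = 0
    member_cols = {}
    for modality in committee.modalities:
        model = committee.members[modality]
        w = committee.weights[modality]
        X = committee.encoder.matrix(modality, cohort).to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError(f"missing {modality} features for prediction")
        pred = model.estimator.predict(X)  # 1 = deceased
        p_live = model.estimator.predict_survive_proba(X)
        votes_deceased += w * (pred == 1)
        votes_living += w * (pred == 0)
        weighted_p += w * p_live
        total_w += w
        member_cols[f"label_{modality}"] = np.where(pred == 1, "deceased", "living")
    survive_score = weighted_p / total_w
    label = np.where(
        votes_living > votes_deceased,
        "living",
        np.where(
            votes_deceased > votes_living,
            "deceased",
            np.where(survive_score > 0.5, "living", "deceased"),
        ),
    )
    out = pd.DataFrame(
        {
            "label": label,
            "survive_score": survive_score,
            "votes_living": votes_living,
            "votes_deceased": votes_deceased,
            **member_cols,
        },
        index=cohort.clinical.index,
    )
    return out


def committee_predict(committee: Committee, cohort: Cohort, patient_id=None):
    """Predict one patient: (label, survive_score).

    With ``patient_id`` omitted the cohort must contain exactly one record.
    """
    if patient_id is None:
        if cohort.n_patients != 1:
            raise ValueError("give patient_id for multi-record cohorts")
        patient_id = cohort.patient_ids[0]
    frame = committee_predict_cohort(committee, cohort.subset([patient_id]))
    row = frame.iloc[0]
    return str(row["label"]), float(row["survive_score"])
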