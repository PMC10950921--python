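"""Confusion-matrix metric suite: ACC, precision, recall, F1, MCC and rank AUC.

The deceased class is the positive class: TP counts patients who deceased and
were predicted to decease.  Headline aggregates are support-weighted means of
the per-class values (per-class and macro values are also reported).

Zero-denominator conventions: precision/recall/F1 are 0 when undefined, MCC
is 0 when any marginal is zero; triggering a convention is noted in the
report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics_from_confusion",
    "auc_score",
    "evaluate_predictions",
    "weighted_f1",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive/negative classes exchanged."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)


@dataclass
class MetricsReport:
    f1: float
    acc: float
    prec: float
    rec: float
    mcc: float
    n: int
    auc: float | None = None
    per_class: dict = field(default_factory=dict)
    macro: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


def confusion(
    labels_true: Sequence, labels_pred: Sequence, positive="deceased"
) -> ConfusionCounts:
    """Count the four confusion cells with the given positive class."""
    t = np.asarray(labels_true, dtype=object)
    p = np.asarray(labels_pred, dtype=object)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    classes = set(t.tolist()) | set(p.tolist())
    if len(classes) > 2:
        raise ValueError(f"labels are not binary: {sorted(map(str, classes))}")
    tpos = t == positive
    ppos = p == positive
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def _class_metrics(tp: int, fp: int, tn: int, fn: int, notes: list) -> dict:
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    rec = tp / (tp + fn) if (tp + fn) else 0.0
    if (tp + fp) == 0 or (tp + fn) == 0:
        notes.append("precision/recall zero-denominator convention used")
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return {"prec": prec, "rec": rec, "f1": f1, "support": tp + fn}


def metrics_from_confusion(c: ConfusionCounts) -> MetricsReport:
    """Threshold metrics from the four counts, per the printed formulas."""
    if c.n == 0:
        raise ValueError("empty confusion matrix")
    notes: list = []
    acc = (c.tp + c.tn) / c.n

    pos = _class_metrics(c.tp, c.fp, c.tn, c.fn, notes)
    neg = _class_metrics(c.tn, c.fn, c.tp, c.fp, notes)

    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = 0.0
        notes.append("MCC zero-marginal convention used")
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)

    supports = np.array([pos["support"], neg["support"]], dtype=float)
    weights = supports / supports.sum()

    def wavg(key: str) -> float:
        return float(weights[0] * pos[key] + weights[1] * neg[key])

    return MetricsReport(
        f1=wavg("f1"),
        acc=acc,
        prec=wavg("prec"),
        rec=wavg("rec"),
        mcc=mcc,
        n=c.n,
        per_class={"positive": pos, "negative": neg},
        macro={k: (pos[k] + neg[k]) / 2 for k in ("prec", "rec", "f1")},
        notes=notes,
    )


def weighted_f1(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Support-weighted F1 for 0/1-encoded labels (1 = positive class)."""
    c = confusion(np.asarray(y_true), np.asarray(y_pred), positive=1)
    return metrics_from_confusion(c).f1


def auc_score(
    labels_true: Sequence, scores: Sequence[float], positive="deceased"
) -> float:
    """Rank-based AUC: P(random positive outscores a random negative), ties
    counted half.  ``scores`` must be oriented toward the positive class."""
    t = np.asarray(labels_true, dtype=object) == positive
    s = np.asarray(scores, dtype=float)
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present in truth")
    ranks = rankdata(s)  # average ranks handle ties at one half
    auc = (ranks[t].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def evaluate_predictions(
    labels_true: Sequence,
    labels_pred: Sequence,
    survive_scores: Sequence[float] | None = None,
    positive="deceased",
) -> MetricsReport:
    """Full metric report; AUC uses 1 - survive score as the deceased score."""
    report = metrics_from_confusion(confusion(labels_true, labels_pred, positive))
    if survive_scores is not None:
        decease_scores = 1.0 - np.asarray(survive_scores, dtype=float)
        try:
            report.auc = auc_score(labels_true, decease_scores, positive)
        except ValueError:
            report.auc = None
            report.notes.append("AUC undefined (single-class truth)")
    return report
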