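"""Cohort cleaning: adult-AML filters, deduplication, race binarization and
3-nearest-neighbor imputation of clinical features.

The fixed pipeline order is: adult/AML filter -> missing-survival filter ->
sample deduplication -> race binarization -> zero-mutation gene pruning ->
KNN imputation.  Records failing several rules are attributed to the first
rule that triggers (each filter only sees the previous filter's survivors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    CATEGORICAL_CLINICAL,
    CLINICAL_FEATURES,
    NUMERIC_CLINICAL,
    RAW_RACE_COLUMN,
    SAMPLE_SITE_COLUMN,
    SAMPLE_TIMEPOINT_COLUMN,
    Cohort,
    normalize_label,
)

__all__ = [
    "CleaningReport",
    "ImputationSpec",
    "ImputationError",
    "filter_adult_aml",
    "filter_missing_survival",
    "deduplicate_samples",
    "binarize_race",
    "prune_silent_genes",
    "impute_knn",
    "run_preprocess",
    "MIN_ADULT_AGE",
    "MIN_BM_BLAST_PCT",
]

#: Adult-AML inclusion thresholds (both inclusive).
MIN_ADULT_AGE = 18.0
MIN_BM_BLAST_PCT = 20.0

CANONICAL_SITE = "bone_marrow_aspirate"
CANONICAL_TIMEPOINT = "de_novo"


class ImputationError(Exception):
    pass


@dataclass
class CleaningReport:
    n_input: int = 0
    n_removed_per_rule: dict = field(default_factory=dict)
    removed_ids: dict = field(default_factory=dict)
    n_output: int = 0
    notes: list = field(default_factory=list)

    def add_rule(self, rule: str, ids: list) -> None:
        self.n_removed_per_rule[rule] = self.n_removed_per_rule.get(rule, 0) + len(ids)
        self.removed_ids.setdefault(rule, []).extend(str(i) for i in ids)

    def merge(self, other: "CleaningReport") -> None:
        for rule, ids in other.removed_ids.items():
            self.add_rule(rule, ids)
        self.notes.extend(other.notes)
        self.n_output = other.n_output


@dataclass
class ImputationSpec:
    """k nearest neighbors on z-scored numeric + simple-matching categorical
    distance; numeric targets take the neighbor mean, categorical targets the
    neighbor majority."""

    k: int = 3
    numeric_scaling: str = "zscore"
    distance: str = "euclidean_plus_matching"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _drop_mask(cohort: Cohort, drop: np.ndarray, rule: str) -> tuple[Cohort, CleaningReport]:
    report = CleaningReport(n_input=cohort.n_patients)
    report.add_rule(rule, list(cohort.clinical.index[drop]))
    out = cohort.subset_positions(np.flatnonzero(~drop))
    report.n_output = out.n_patients
    return out, report


def filter_adult_aml(cohort: Cohort) -> tuple[Cohort, CleaningReport]:
    """Keep adult AML records: diagnosis age >= 18 and bone-marrow blasts >= 20%.

    Records missing either field are removed by this rule (they cannot be
    shown to meet the case definition).
    """
    clin = cohort.clinical
    age = pd.to_numeric(clin.get("diagnosis_age"), errors="coerce")
    blast = pd.to_numeric(clin.get("bm_blast_pct"), errors="coerce")
    bad_age = age.isna() | (age < MIN_ADULT_AGE)
    bad_blast = blast.isna() | (blast < MIN_BM_BLAST_PCT)
    report = CleaningReport(n_input=cohort.n_patients)
    report.add_rule("underage_or_missing_age", list(clin.index[bad_age]))
    report.add_rule("low_bm_blast_or_missing", list(clin.index[~bad_age & bad_blast]))
    keep_mask = (~bad_age & ~bad_blast).to_numpy()
    out = cohort.subset_positions(np.flatnonzero(keep_mask))
    report.n_output = out.n_patients
    return out, report


def filter_missing_survival(cohort: Cohort) -> tuple[Cohort, CleaningReport]:
    """Remove records with no overall survival status (the class label)."""
    missing = cohort.clinical["overall_survival_status"].isna().to_numpy()
    return _drop_mask(cohort, missing, "missing_survival")


def deduplicate_samples(
    cohort: Cohort,
    site_field: str = SAMPLE_SITE_COLUMN,
    timepoint_field: str = SAMPLE_TIMEPOINT_COLUMN,
) -> tuple[Cohort, CleaningReport]:
    """Drop non-marrow and non-de-novo samples, then enforce one record per id.

    Sample-level metadata is optional: cohorts without the metadata columns
    pass through unchanged (with a logged notice), since every remaining record
    is then a diagnosis-time marrow record by assumption.
    """
    clin = cohort.clinical
    report = CleaningReport(n_input=cohort.n_patients)
    # positional masks throughout: ids may be duplicated at this stage
    keep = np.ones(len(clin), dtype=bool)

    if site_field in clin.columns:
        site = clin[site_field].map(normalize_label).to_numpy(dtype=object)
        bad = np.array([s == s and s != CANONICAL_SITE for s in site], dtype=bool)
        report.add_rule("non_marrow_site", list(clin.index[bad]))
        keep &= ~bad
    else:
        report.notes.append(f"no {site_field!r} column; site filter vacuous")

    if timepoint_field in clin.columns:
        tp = clin[timepoint_field].map(normalize_label).to_numpy(dtype=object)
        bad = np.array(
            [t == t and t != CANONICAL_TIMEPOINT for t in tp], dtype=bool
        ) & keep
        report.add_rule("non_de_novo_timepoint", list(clin.index[bad]))
        keep &= ~bad
    else:
        report.notes.append(f"no {timepoint_field!r} column; timepoint filter vacuous")

    pos = np.flatnonzero(keep)
    ids_kept = clin.index[pos]
    dup_mask = pd.Series(ids_kept).duplicated().to_numpy()
    report.add_rule("duplicate_patient", list(ids_kept[dup_mask]))
    pos = pos[~dup_mask]

    out = Cohort(
        clinical=cohort.clinical.iloc[pos].copy(),
        mutations=cohort.mutations.iloc[pos].copy(),
        expression=cohort.expression.iloc[pos].copy(),
        provenance=dict(cohort.provenance),
    )
    report.n_output = out.n_patients
    return out, report


def binarize_race(cohort: Cohort) -> Cohort:
    """Map the raw race label to the binary is_white flag (1 iff "white").

    Missing race stays missing for the imputation stage.  If the cohort
    already carries is_white and no raw race column, this is the identity.
    """
    out = cohort.copy()
    clin = out.clinical
    if RAW_RACE_COLUMN in clin.columns:
        race = clin[RAW_RACE_COLUMN].map(normalize_label)
        is_white = pd.Series(np.nan, index=clin.index, dtype=float)
        is_white[race.notna()] = (race[race.notna()] == "white").astype(float)
        clin["is_white"] = is_white
        out.clinical = clin.drop(columns=[RAW_RACE_COLUMN])
    return out


def prune_silent_genes(cohort: Cohort) -> tuple[Cohort, list[str]]:
    """Drop mutation-panel genes with zero mutations across the cohort."""
    counts = cohort.mutations.fillna(0).sum(axis=0)
    silent = [g for g in cohort.mutations.columns if counts[g] == 0]
    out = cohort.copy()
    out.mutations = out.mutations.drop(columns=silent)
    return out, silent


def _mixed_distance(
    target_mask: np.ndarray,
    numeric: np.ndarray,
    categorical: np.ndarray,
) -> np.ndarray:
    """Pairwise squared distance of masked rows to complete rows.

    numeric is already z-scored; categorical contributes 1 per mismatch
    (simple matching).
    """
    a_num = numeric[target_mask]
    b_num = numeric[~target_mask]
    d2 = ((a_num[:, None, :] - b_num[None, :, :]) ** 2).sum(axis=2)
    if categorical.shape[1]:
        a_cat = categorical[target_mask]
        b_cat = categorical[~target_mask]
        d2 = d2 + (a_cat[:, None, :] != b_cat[None, :, :]).sum(axis=2)
    return d2


def impute_knn(cohort: Cohort, spec: ImputationSpec | None = None) -> Cohort:
    """Fill missing clinical cells from the k nearest complete records.

    Each clinical feature with missing entries is treated in turn as the
    prediction target; distances are measured on the clinical features that
    are complete across the whole cohort (Euclidean on z-scored numerics plus
    simple matching on categoricals).  Numeric targets receive the neighbor
    mean, categorical targets the neighbor majority (ties broken by the
    cohort-wide modal category).  Genetic tables are untouched.
    """
    spec = spec or ImputationSpec()
    out = cohort.copy()
    clin = out.clinical

    feat_cols = [c for c in CLINICAL_FEATURES if c in clin.columns]
    targets = [c for c in feat_cols if clin[c].isna().any()]
    if not targets:
        return out

    complete_cols = [c for c in feat_cols if not clin[c].isna().any()]

    for target in targets:
        predictors = [c for c in complete_cols if c != target]
        num_cols = [c for c in predictors if c in NUMERIC_CLINICAL]
        cat_cols = [c for c in predictors if c in CATEGORICAL_CLINICAL]

        num = clin[num_cols].to_numpy(dtype=float) if num_cols else np.empty((len(clin), 0))
        if num.shape[1]:
            mu = num.mean(axis=0)
            sd = num.std(axis=0)
            sd[sd == 0] = 1.0
            num = (num - mu) / sd
        cat = (
            clin[cat_cols].astype(object).to_numpy()
            if cat_cols
            else np.empty((len(clin), 0), dtype=object)
        )

        missing_mask = clin[target].isna().to_numpy()
        donors_mask = ~missing_mask
        if donors_mask.sum() < spec.k:
            raise ImputationError(
                f"feature {target!r}: only {int(donors_mask.sum())} complete "
                f"records, need k={spec.k}"
            )
        d2 = _mixed_distance(missing_mask, num, cat)
        # stable argsort keeps input order on distance ties
        order = np.argsort(d2, axis=1, kind="stable")[:, : spec.k]
        donor_idx = np.flatnonzero(donors_mask)

        values = clin[target].to_numpy()
        donor_vals = values[donors_mask]
        fills = []
        if target in NUMERIC_CLINICAL:
            for row in order:
                fills.append(float(np.mean(donor_vals[row].astype(float))))
        else:
            overall = pd.Series(donor_vals).mode()
            modal = overall.iloc[0] if len(overall) else np.nan
            for row in order:
                counts: dict = {}
                for v in donor_vals[row]:
                    counts[v] = counts.get(v, 0) + 1
                best = max(counts.values())
                winners = [v for v, c in counts.items() if c == best]
                if len(winners) == 1:
                    fills.append(winners[0])
                elif modal in winners:
                    fills.append(modal)  # cohort-modal category breaks ties
                else:
                    fills.append(min(winners, key=str))
        col = clin[target].copy()
        col.iloc[np.flatnonzero(missing_mask)] = fills
        clin[target] = col
        del donor_idx
    out.clinical = clin
    return out


def run_preprocess(
    cohort: Cohort,
    spec: ImputationSpec | None = None,
    *,
    site_field: str = SAMPLE_SITE_COLUMN,
    timepoint_field: str = SAMPLE_TIMEPOINT_COLUMN,
) -> tuple[Cohort, CleaningReport]:
    """Run the full cleaning chain in its fixed order."""
    report = CleaningReport(n_input=cohort.n_patients)
    cohort, r = filter_adult_aml(cohort)
    report.merge(r)
    cohort, r = filter_missing_survival(cohort)
    report.merge(r)
    cohort, r = deduplicate_samples(cohort, site_field, timepoint_field)
    report.merge(r)
    cohort = binarize_race(cohort)
    cohort, silent = prune_silent_genes(cohort)
    if silent:
        report.notes.append(f"pruned {len(silent)} silent mutation genes")
    cohort = impute_knn(cohort, spec)
    report.n_output = cohort.n_patients
    return cohort, report
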