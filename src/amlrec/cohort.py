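"""Domain types and I/O for three-modality AML patient cohorts.

A cohort joins three tables keyed by patient id: a clinical table (demographics,
blood counts, risk stratification, treatment-intensity group and the survival
label), a binary gene-mutation matrix and a continuous gene-expression matrix.
Tables are held as :class:`pandas.DataFrame` objects indexed by patient id;
missing values are :data:`numpy.nan` regardless of the on-disk marker.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Protocol",
    "PatientRecord",
    "Cohort",
    "Violation",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "CohortError",
    "SchemaError",
    "ParseError",
    "CLINICAL_FEATURES",
    "NUMERIC_CLINICAL",
    "CATEGORICAL_CLINICAL",
    "ELN_CATEGORIES",
    "GENDER_CATEGORIES",
    "SURVIVAL_CATEGORIES",
    "DEFAULT_MISSING_MARKERS",
    "normalize_label",
]

#: Canonical clinical schema: the 11 expert-curated features, the last one being
#: the class label (overall survival status).
CLINICAL_FEATURES: tuple[str, ...] = (
    "diagnosis_age",
    "bm_blast_pct",
    "mutation_count",
    "pb_blast_pct",
    "wbc",
    "gender",
    "is_white",
    "cytogenetic_group",
    "eln_risk",
    "treatment_intensity",
    "overall_survival_status",
)

NUMERIC_CLINICAL: tuple[str, ...] = (
    "diagnosis_age",
    "bm_blast_pct",
    "mutation_count",
    "pb_blast_pct",
    "wbc",
)

CATEGORICAL_CLINICAL: tuple[str, ...] = (
    "gender",
    "is_white",
    "cytogenetic_group",
    "eln_risk",
    "treatment_intensity",
    "overall_survival_status",
)

ELN_CATEGORIES: tuple[str, ...] = ("favorable", "intermediate", "adverse")
GENDER_CATEGORIES: tuple[str, ...] = ("male", "female")
SURVIVAL_CATEGORIES: tuple[str, ...] = ("living", "deceased")

#: On-disk markers mapped to the internal missing state (case-insensitive).
DEFAULT_MISSING_MARKERS: tuple[str, ...] = ("", "NA", "n/a", "N/A", "na", "NaN", "nan")

ID_COLUMN = "patient_id"

# Optional sample-level metadata columns used by the deduplication filters.
SAMPLE_SITE_COLUMN = "sample_site"
SAMPLE_TIMEPOINT_COLUMN = "sample_timepoint"
RAW_RACE_COLUMN = "race"


class CohortError(Exception):
    """Base class for cohort I/O and schema failures."""


class SchemaError(CohortError):
    """Header-level problem, e.g. duplicated column names."""


class ParseError(CohortError):
    """A cell could not be parsed; the message names row and column."""


class Protocol(enum.Enum):
    """The four expert-defined treatment-intensity groups.

    The definition order is the canonical order used for deterministic
    tie-breaking only (less burdensome protocols first); it carries no
    clinical ranking.
    """

    TARGET = "target"
    REGULAR = "regular"
    LOW_INTENSITY = "low_intensity"
    HIGH_INTENSITY = "high_intensity"

    @classmethod
    def canonical_order(cls) -> tuple["Protocol", ...]:
        return tuple(cls)

    @classmethod
    def labels(cls) -> tuple[str, ...]:
        return tuple(p.value for p in cls)


_LABEL_RE = re.compile(r"[^0-9a-z]+")


def normalize_label(value: object) -> object:
    """Normalize a category label to lower snake case.

    Missing values pass through unchanged so downstream imputation can see
    them.  Non-string scalars (e.g. the 0/1 race flag) are returned as-is.
    """
    if not isinstance(value, str):
        return value
    out = _LABEL_RE.sub("_", value.strip().lower()).strip("_")
    return out


@dataclass
class PatientRecord:
    """A single patient's values across the three modalities."""

    patient_id: str
    diagnosis_age: float
    bm_blast_pct: float
    mutation_count: float
    pb_blast_pct: float
    wbc: float
    gender: object
    is_white: object
    cytogenetic_group: object
    eln_risk: object
    treatment_intensity: object
    overall_survival_status: object
    mutations: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)

    def clinical_row(self) -> pd.Series:
        return pd.Series(
            {name: getattr(self, name) for name in CLINICAL_FEATURES},
            name=self.patient_id,
        )


@dataclass
class Cohort:
    """A validated-by-convention collection of patient records.

    ``clinical``, ``mutations`` and ``expression`` share the patient-id index.
    Panels are the column orderings of the genetic tables; the clinical schema
    is the clinical column ordering (extra sample-metadata columns such as
    ``sample_site`` are carried alongside and ignored by modeling).
    """

    clinical: pd.DataFrame
    mutations: pd.DataFrame
    expression: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    @property
    def clinical_schema(self) -> list[str]:
        return [c for c in self.clinical.columns if c in CLINICAL_FEATURES]

    @property
    def mutation_panel(self) -> list[str]:
        return list(self.mutations.columns)

    @property
    def expression_panel(self) -> list[str]:
        return list(self.expression.columns)

    def copy(self) -> "Cohort":
        return Cohort(
            clinical=self.clinical.copy(),
            mutations=self.mutations.copy(),
            expression=self.expression.copy(),
            provenance=dict(self.provenance),
        )

    def subset(self, ids: Sequence[str]) -> "Cohort":
        ids = list(ids)
        return Cohort(
            clinical=self.clinical.loc[ids].copy(),
            mutations=self.mutations.loc[ids].copy(),
            expression=self.expression.loc[ids].copy(),
            provenance=dict(self.provenance),
        )

    def subset_positions(self, positions: Sequence[int]) -> "Cohort":
        """Row-positional subset; safe while patient ids are still duplicated."""
        positions = list(positions)
        return Cohort(
            clinical=self.clinical.iloc[positions].copy(),
            mutations=self.mutations.iloc[positions].copy(),
            expression=self.expression.iloc[positions].copy(),
            provenance=dict(self.provenance),
        )

    def record(self, patient_id: str) -> PatientRecord:
        row = self.clinical.loc[patient_id]
        if isinstance(row, pd.DataFrame):  # duplicated id: take first, stable
            row = row.iloc[0]
        kwargs = {name: row.get(name, np.nan) for name in CLINICAL_FEATURES}
        mut = self.mutations.loc[patient_id]
        exp = self.expression.loc[patient_id]
        if isinstance(mut, pd.DataFrame):
            mut = mut.iloc[0]
        if isinstance(exp, pd.DataFrame):
            exp = exp.iloc[0]
        return PatientRecord(
            patient_id=str(patient_id),
            mutations=mut.to_dict(),
            expression=exp.to_dict(),
            **kwargs,
        )

    def records(self) -> Iterator[PatientRecord]:
        for pid in self.patient_ids:
            yield self.record(pid)


def _read_table(
    path: Path,
    delimiter: str,
    missing_markers: Sequence[str],
) -> pd.DataFrame:
    header = pd.read_csv(path, sep=delimiter, nrows=0)
    raw_names = [c for c in header.columns]
    # pandas mangles duplicates to name.1; detect them on the raw header line
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split(delimiter)
    if len(set(first)) != len(first):
        dupes = sorted({c for c in first if first.count(c) > 1})
        raise SchemaError(f"{path}: duplicated header names {dupes}")
    del raw_names
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        na_values=list(missing_markers),
        keep_default_na=False,
        skipinitialspace=True,
    )
    return df


def _coerce_numeric(df: pd.DataFrame, columns: Sequence[str], path: str) -> None:
    for col in columns:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in numeric column {col!r} at data row {row}"
            )
        df[col] = coerced


def read_cohort(
    clinical_path: str | Path,
    mutation_path: str | Path,
    expression_path: str | Path,
    *,
    delimiter: str = "\t",
    missing_markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
    genes_as_rows: bool = False,
) -> Cohort:
    """Read and join the three modality tables on patient id.

    Rows present in one modality but not another are retained with their
    missing modality flagged as all-missing (never silently dropped); the ids
    are recorded in ``provenance['unmatched']``.  Category labels in the
    clinical table are normalized to lower snake case; the original strings
    are kept in ``provenance['original_labels']``.

    ``genes_as_rows`` transposes the genetic tables at load, for exports that
    store genes as rows and patients as columns.
    """
    clinical_path, mutation_path, expression_path = (
        Path(clinical_path), Path(mutation_path), Path(expression_path),
    )
    clin = _read_table(clinical_path, delimiter, missing_markers)
    if ID_COLUMN not in clin.columns:
        clin = clin.rename(columns={clin.columns[0]: ID_COLUMN})
    clin = clin.set_index(ID_COLUMN)
    _coerce_numeric(clin, NUMERIC_CLINICAL + ("is_white",), str(clinical_path))

    original_labels: dict[str, dict[str, str]] = {}
    for col in clin.columns:
        if col in NUMERIC_CLINICAL or col == "is_white":
            continue
        raw = clin[col]
        norm = raw.map(normalize_label)
        changed = {
            str(r): str(n)
            for r, n in zip(raw, norm)
            if isinstance(r, str) and r != n
        }
        if changed:
            original_labels[col] = changed
        clin[col] = norm

    genetic = {}
    for name, path in (("mutations", mutation_path), ("expression", expression_path)):
        df = _read_table(path, delimiter, missing_markers)
        first_col = df.columns[0]
        df = df.set_index(first_col)
        if genes_as_rows:
            df = df.T
        df.index.name = ID_COLUMN
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"{path}: non-numeric value {df[col].iloc[row]!r} "
                    f"in column {col!r} at data row {row}"
                )
            df[col] = coerced
        genetic[name] = df

    all_ids = list(clin.index)
    seen = set(all_ids)
    unmatched: dict[str, list[str]] = {}
    for name, df in genetic.items():
        extra = [i for i in df.index if i not in seen]
        if extra:
            all_ids.extend(extra)
            seen.update(extra)
    clin = clin.reindex(all_ids)
    for name in genetic:
        missing_ids = [i for i in all_ids if i not in set(genetic[name].index)]
        if missing_ids:
            unmatched[name] = missing_ids
        genetic[name] = genetic[name].reindex(all_ids)

    provenance = {
        "sources": {
            "clinical": str(clinical_path),
            "mutations": str(mutation_path),
            "expression": str(expression_path),
        },
        "unmatched": unmatched,
        "original_labels": original_labels,
    }
    return Cohort(
        clinical=clin,
        mutations=genetic["mutations"],
        expression=genetic["expression"],
        provenance=provenance,
    )


def write_cohort(
    cohort: Cohort,
    out_dir: str | Path,
    *,
    delimiter: str = "\t",
) -> dict[str, Path]:
    """Write the three modality tables; inverse of :func:`read_cohort`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": out_dir / "clinical.tsv",
        "mutations": out_dir / "mutations.tsv",
        "expression": out_dir / "expression.tsv",
    }
    for name, path in paths.items():
        frame = getattr(cohort, name)
        frame = frame.rename_axis(ID_COLUMN)
        frame.to_csv(path, sep=delimiter, na_rep="")
    return paths


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_cohort`."""

    kind: str
    patient_id: str | None
    field: str | None
    message: str


def _check_range(df, col, lo, hi, kind, out):
    if col not in df.columns:
        return
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = (vals < lo) | (vals > hi)
    for pid in df.index[bad.fillna(False)]:
        out.append(Violation(kind, str(pid), col,
                             f"{col}={df.loc[pid, col]!r} outside [{lo}, {hi}]"))


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check cohort invariants; returns one descriptor per violation.

    Checked: unique patient ids; blast percentages in [0, 100]; non-negative
    WBC and mutation count; known ELN, gender, survival and protocol
    categories; mutation flags in {0, 1}.  Missing values are not violations
    (preprocessing handles them).
    """
    out: list[Violation] = []
    clin = cohort.clinical

    counts = pd.Series(clin.index).value_counts()
    for pid in counts.index[counts > 1]:
        out.append(Violation("duplicate_id", str(pid), None,
                             f"patient_id {pid!r} appears {counts[pid]} times"))

    _check_range(clin, "bm_blast_pct", 0, 100, "range", out)
    _check_range(clin, "pb_blast_pct", 0, 100, "range", out)
    _check_range(clin, "wbc", 0, np.inf, "range", out)
    _check_range(clin, "mutation_count", 0, np.inf, "range", out)

    category_domains = {
        "eln_risk": set(ELN_CATEGORIES),
        "gender": set(GENDER_CATEGORIES),
        "treatment_intensity": set(Protocol.labels()),
        "overall_survival_status": set(SURVIVAL_CATEGORIES),
    }
    for col, domain in category_domains.items():
        if col not in clin.columns:
            continue
        for pid, val in clin[col].items():
            if pd.isna(val):
                continue
            if val not in domain:
                out.append(Violation("unknown_category", str(pid), col,
                                     f"{col}={val!r} not in {sorted(domain)}"))

    if "is_white" in clin.columns:
        vals = clin["is_white"]
        for pid, val in vals.items():
            if pd.isna(val):
                continue
            if val not in (0, 1):
                out.append(Violation("binary_flag", str(pid), "is_white",
                                     f"is_white={val!r} not in {{0, 1}}"))

    mut = cohort.mutations.to_numpy(dtype=float)
    bad_mask = ~(np.isnan(mut) | (mut == 0) | (mut == 1))
    for i, j in zip(*np.nonzero(bad_mask)):
        out.append(Violation(
            "mutation_flag", str(cohort.mutations.index[i]),
            str(cohort.mutations.columns[j]),
            f"mutation value {mut[i, j]!r} not in {{0, 1}}"))
    return out
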