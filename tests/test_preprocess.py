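import numpy as np
import pandas as pd
import pytest

from amlrec import (
    CleaningReport,
    ImputationSpec,
    binarize_race,
    deduplicate_samples,
    filter_adult_aml,
    filter_missing_survival,
    impute_knn,
    run_preprocess,
)
from amlrec.cohort import Cohort
from amlrec.preprocess import ImputationError, prune_silent_genes
from amlrec.synthetic import make_dirty_fixture


def _cohort_from_clinical(clin: pd.DataFrame) -> Cohort:
    idx = clin.index
    genes = pd.DataFrame({"TP53": np.zeros(len(idx), dtype=int)}, index=idx)
    expr = pd.DataFrame({"XIST": np.zeros(len(idx))}, index=idx)
    return Cohort(clinical=clin, mutations=genes, expression=expr)


def _clin(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df.index = [f"P{i}" for i in range(len(df))]
    df.index.name = "patient_id"
    return df


class TestAdultAmlFilter:
    def test_age_boundary_inclusive_at_18(self):
        cohort = _cohort_from_clinical(_clin({
            "diagnosis_age": [17.0, 18.0, 40.0],
            "bm_blast_pct": [50.0, 50.0, 50.0],
            "overall_survival_status": ["living"] * 3,
        }))
        kept, report = filter_adult_aml(cohort)
        assert kept.clinical["diagnosis_age"].tolist() == [18.0, 40.0]
        assert report.n_removed_per_rule["underage_or_missing_age"] == 1

    def test_blast_boundary_inclusive_at_20(self):
        cohort = _cohort_from_clinical(_clin({
            "diagnosis_age": [30.0, 30.0, 30.0],
            "bm_blast_pct": [19.9, 20.0, 80.0],
            "overall_survival_status": ["living"] * 3,
        }))
        kept, _ = filter_adult_aml(cohort)
        assert kept.clinical["bm_blast_pct"].tolist() == [20.0, 80.0]

    def test_missing_age_or_blast_removed(self):
        cohort = _cohort_from_clinical(_clin({
            "diagnosis_age": [np.nan, 30.0],
            "bm_blast_pct": [50.0, np.nan],
            "overall_survival_status": ["living"] * 2,
        }))
        kept, report = filter_adult_aml(cohort)
        assert kept.n_patients == 0
        assert report.n_removed_per_rule["underage_or_missing_age"] == 1
        assert report.n_removed_per_rule["low_bm_blast_or_missing"] == 1

    def test_idempotent(self, small_cohort):
        cohort, _ = small_cohort
        once, _ = filter_adult_aml(cohort)
        twice, report = filter_adult_aml(once)
        assert twice.patient_ids == once.patient_ids
        assert sum(report.n_removed_per_rule.values()) == 0


class TestSurvivalFilter:
    def test_missing_markers_all_removed(self):
        cohort = _cohort_from_clinical(_clin({
            "diagnosis_age": [30.0] * 4,
            "bm_blast_pct": [50.0] * 4,
            "overall_survival_status": ["living", np.nan, "deceased", np.nan],
        }))
        kept, report = filter_missing_survival(cohort)
        assert kept.n_patients == 2
        assert report.n_removed_per_rule["missing_survival"] == 2

    def test_identity_when_all_present(self, small_cohort):
        cohort, _ = small_cohort
        kept, _ = filter_missing_survival(cohort)
        assert kept.patient_ids == cohort.patient_ids


class TestDeduplicate:
    def test_non_marrow_and_relapse_samples_removed(self):
        clin = _clin({
            "diagnosis_age": [30.0] * 3,
            "bm_blast_pct": [50.0] * 3,
            "overall_survival_status": ["living"] * 3,
            "sample_site": ["Bone Marrow Aspirate", "Peripheral Blood",
                            "bone_marrow_aspirate"],
            "sample_timepoint": ["de novo", "de novo", "Relapse"],
        })
        cohort = _cohort_from_clinical(clin)
        kept, report = deduplicate_samples(cohort)
        assert kept.patient_ids == ["P0"]
        assert report.n_removed_per_rule["non_marrow_site"] == 1
        assert report.n_removed_per_rule["non_de_novo_timepoint"] == 1

    def test_duplicate_patient_keeps_first_by_input_order(self):
        clin = _clin({
            "diagnosis_age": [30.0, 40.0],
            "bm_blast_pct": [50.0, 60.0],
            "overall_survival_status": ["living", "deceased"],
        })
        clin.index = ["X", "X"]
        cohort = _cohort_from_clinical(clin)
        kept, report = deduplicate_samples(cohort)
        assert kept.n_patients == 1
        assert kept.clinical["diagnosis_age"].iloc[0] == 30.0
        assert report.n_removed_per_rule["duplicate_patient"] == 1

    def test_vacuous_without_metadata_logs_notice(self, small_cohort):
        cohort, _ = small_cohort
        kept, report = deduplicate_samples(cohort)
        assert kept.patient_ids == cohort.patient_ids
        assert len(report.notes) == 2


class TestBinarizeRace:
    @pytest.mark.parametrize(
        "raw,expected", [("White", 1.0), ("asian", 0.0), (np.nan, np.nan)]
    )
    def test_white_maps_to_one_else_zero_missing_kept(self, raw, expected):
        clin = _clin({
            "diagnosis_age": [30.0],
            "bm_blast_pct": [50.0],
            "race": [raw],
            "overall_survival_status": ["living"],
        })
        out = binarize_race(_cohort_from_clinical(clin))
        got = out.clinical["is_white"].iloc[0]
        assert got == expected or (np.isnan(got) and np.isnan(expected))
        assert "race" not in out.clinical.columns


class TestImputeKnn:
    def test_identity_without_missing(self, small_cohort):
        cohort, _ = small_cohort
        out = impute_knn(cohort)
        pd.testing.assert_frame_equal(out.clinical, cohort.clinical)

    def test_numeric_fill_is_neighbor_mean_on_forced_distances(self):
        # P3 missing WBC; its three exact twins carry WBC {10, 20, 30}
        clin = _clin({
            "diagnosis_age": [50.0, 50.0, 50.0, 50.0, 80.0],
            "bm_blast_pct": [60.0, 60.0, 60.0, 60.0, 95.0],
            "wbc": [10.0, 20.0, 30.0, np.nan, 400.0],
            "gender": ["male"] * 4 + ["female"],
            "overall_survival_status": ["living"] * 5,
        })
        out = impute_knn(_cohort_from_clinical(clin), ImputationSpec(k=3))
        assert out.clinical["wbc"].iloc[3] == pytest.approx(20.0)

    def test_categorical_fill_is_neighbor_majority(self):
        clin = _clin({
            "diagnosis_age": [50.0, 50.0, 50.0, 50.0, 80.0],
            "bm_blast_pct": [60.0] * 4 + [95.0],
            "gender": ["male", "male", "female", np.nan, "female"],
            "overall_survival_status": ["living"] * 5,
        })
        out = impute_knn(_cohort_from_clinical(clin), ImputationSpec(k=3))
        assert out.clinical["gender"].iloc[3] == "male"

    def test_too_few_complete_records_raises(self):
        clin = _clin({
            "diagnosis_age": [50.0, 50.0],
            "wbc": [np.nan, 10.0],
            "overall_survival_status": ["living"] * 2,
        })
        with pytest.raises(ImputationError, match="wbc"):
            impute_knn(_cohort_from_clinical(clin), ImputationSpec(k=3))

    def test_no_missing_clinical_cells_after_imputation(self, small_cohort):
        from amlrec import inject_missingness

        cohort, _ = small_cohort
        holey = inject_missingness(cohort, rate=0.08, seed=5)
        out = impute_knn(holey)
        feature_cols = [c for c in out.clinical.columns]
        assert not out.clinical[feature_cols].isna().any().any()


class TestPruneSilentGenes:
    def test_zero_mutation_columns_dropped(self, small_cohort):
        cohort, _ = small_cohort
        with_silent = cohort.copy()
        with_silent.mutations = with_silent.mutations.copy()
        with_silent.mutations["NEVERMUT"] = 0
        out, silent = prune_silent_genes(with_silent)
        assert "NEVERMUT" in silent
        assert "NEVERMUT" not in out.mutation_panel
        assert (out.mutations.sum(axis=0) > 0).all()


class TestFullChain:
    def test_dirty_fixture_attribution_matches_manifest(self):
        fixture = make_dirty_fixture(seed=4)
        clean, report = run_preprocess(fixture.cohort)
        assert report.n_input == fixture.manifest["n_input"]
        assert clean.n_patients == fixture.manifest["n_clean"]
        for rule, ids in fixture.manifest["removed"].items():
            assert sorted(report.removed_ids[rule]) == sorted(ids), rule
        # the double-violation record is charged to the first rule only
        multi = fixture.manifest["multi_rule_ids"][0]
        assert multi in report.removed_ids["underage_or_missing_age"]
        assert multi not in report.removed_ids["low_bm_blast_or_missing"]

    def test_chain_never_increases_records_or_leaves_missing(self, small_cohort):
        from amlrec import inject_missingness

        cohort, _ = small_cohort
        holey = inject_missingness(cohort, rate=0.05, seed=9)
        clean, report = run_preprocess(holey)
        assert clean.n_patients <= cohort.n_patients
        assert not clean.clinical.isna().any().any()
        assert report.n_output == clean.n_patients
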