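import numpy as np
import pandas as pd
import pytest

from amlrec import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient clean cohort with small decoy panels (session-cached)."""
    config = GeneratorConfig(
        n_patients=60, n_decoy_expression=8, n_decoy_mutation=5, seed=11
    )
    cohort, truth = generate_cohort(config)
    return cohort, truth


@pytest.fixture()
def tiny_tables(tmp_path):
    """Hand-written three-table fixture: clinical ids {A, B}, genetic only A."""
    clinical = tmp_path / "clinical.tsv"
    mutations = tmp_path / "mutations.tsv"
    expression = tmp_path / "expression.tsv"
    clinical.write_text(
        "patient_id\tdiagnosis_age\tbm_blast_pct\tmutation_count\t"
        "pb_blast_pct\twbc\tgender\tis_white\tcytogenetic_group\teln_risk\t"
        "treatment_intensity\toverall_survival_status\n"
        "A\t45\t60\t5\t30\t12.5\tMale\t1\tNormal Karyotype\tfavorable\t"
        "regular\tliving\n"
        "B\t62\t85\t9\t44\tn/a\tFemale\t0\tComplex\tadverse\t"
        "high_intensity\tdeceased\n"
    )
    mutations.write_text("patient_id\tTP53\tSRSF2\nA\t1\t0\n")
    expression.write_text("patient_id\tXIST\tMX1\nA\t0.5\t-1.25\n")
    return clinical, mutations, expression
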