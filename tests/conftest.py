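import numpy as np
import pandas as pd
import pytest

from lepmel.simulate import study_like_config, simulate_cohort


TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t1000\trsA\tT\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t2000\trsB\tG\tA\t.\tPASS\t.\tGT\t0|1\t./.\t0/.
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)


@pytest.fixture
def toy_phenotypes(tmp_path):
    df = pd.DataFrame({
        "sample_id": ["S1", "S2", "S3"],
        "status": ["case", "control", "case"],
        "sex": ["boy", "girl", "boy"],
        "age_group": ["7-8", "11-14", "15-18"],
        "school": ["primary-2", "junior-1", "senior-1"],
        "maternal_edu": ["high_school_or_below"] * 3,
        "paternal_edu": ["junior_college_or_above"] * 3,
        "income": ["<5000", "5000-9999", ">=10000"],
        "physical_activity": ["adequate", "inadequate", ""],
        "sleep": ["inadequate", "", "adequate"],
    })
    path = tmp_path / "pheno.tsv"
    df.to_csv(path, sep="\t", index=False)
    return str(path)


@pytest.fixture(scope="session")
def small_cohort():
    """Study-like synthetic cohort, scaled down for fast tests."""
    cfg = study_like_config(n_cases=400, n_controls=440, seed=11)
    cohort, _ = simulate_cohort(cfg, n_pool=12000)
    return cohort


@pytest.fixture(scope="session")
def small_config():
    return study_like_config(n_cases=400, n_controls=440, seed=11)
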