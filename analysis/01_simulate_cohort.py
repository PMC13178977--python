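"""Generate the study-like synthetic cohort used by every later step.

Emulates a frequency-matched case-control study of childhood obesity:
1123 cases / 1231 controls, 12 candidate variants in the
leptin-melanocortin pathway (four carrying per-allele log-odds effects
0.268 / 0.217 / 0.110 / 0.044), lifestyle exposures with ~86% inadequate
physical activity and ~80% inadequate sleep, and controls
frequency-matched to cases on sex, age group and school.  Writes a VCF,
a phenotype TSV and a pipeline config under results/synthetic_cohort/.
"""

import pandas as pd

from lepmel.pipeline import make_fixture

OUT = "results/synthetic_cohort"
SEED = 20250922


def main() -> None:
    paths = make_fixture(OUT, seed=SEED)
    pheno = pd.read_csv(paths["phenotypes"], sep="\t")
    n_case = (pheno["status"] == "case").sum()
    n_ctrl = (pheno["status"] == "control").sum()
    print(f"wrote {paths['vcf']} and {paths['phenotypes']}")
    print(f"cohort: {n_case} cases / {n_ctrl} controls")
    for col in ("sex", "age_group"):
        tab = pd.crosstab(pheno[col], pheno["status"], normalize="columns")
        print(f"\nfrequency matching on {col} (column proportions):")
        print(tab.round(3).to_string())
    for col in ("physical_activity", "sleep"):
        prev = (pheno[col] == "inadequate").mean()
        print(f"{col}: {prev:.1%} inadequate "
              f"({pheno[col].isna().sum()} missing)")


if __name__ == "__main__":
    main()
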