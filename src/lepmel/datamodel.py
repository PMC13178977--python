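"""Core domain types and the cohort-table vocabulary.

The analysis frame ("cohort table") is a plain :class:`pandas.DataFrame`
with one row per sample: phenotype/covariate columns listed in
:data:`PHENOTYPE_COLUMNS`, plus one float column per variant holding the
ALT-allele dosage (0/1/2, ``NaN`` for missing calls).  Risk-allele
orientation is applied downstream, never at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: covariates of the standard adjustment set (all categorical)
ADJUSTMENT_COVARIATES = ["age_group", "sex", "maternal_edu", "paternal_edu", "income"]

#: binary lifestyle exposures; "inadequate" is the at-risk level
LIFESTYLE_COLUMNS = ["physical_activity", "sleep"]

PHENOTYPE_COLUMNS = ["sample_id", "status", "sex", "age_group", "school",
                     "maternal_edu", "paternal_edu", "income"] + LIFESTYLE_COLUMNS

#: declared level vocabulary per categorical phenotype column
VOCABULARY: dict[str, list[str]] = {
    "sex": ["boy", "girl"],
    "age_group": ["7-8", "11-14", "15-18"],
    "school": ["primary-2", "junior-1", "senior-1"],
    "maternal_edu": ["high_school_or_below", "junior_college_or_above"],
    "paternal_edu": ["high_school_or_below", "junior_college_or_above"],
    "income": ["<5000", "5000-9999", ">=10000"],
    "physical_activity": ["adequate", "inadequate"],
    "sleep": ["adequate", "inadequate"],
}

#: columns that may carry missing values without dropping the row
NULLABLE_COLUMNS = set(LIFESTYLE_COLUMNS)

STATUS_CODES = {"case": 1, "control": 0, "1": 1, "0": 0}


@dataclass
class VariantInfo:
    """Identity and QC-relevant metadata for one biallelic locus."""

    variant_id: str
    ref_allele: str
    alt_allele: str
    risk_allele: Optional[str] = None
    maf: Optional[float] = None
    call_rate: Optional[float] = None
    gene_label: str = ""

    def __post_init__(self) -> None:
        if self.risk_allele is not None and self.risk_allele not in (
            self.ref_allele, self.alt_allele
        ):
            raise ValueError(
                f"{self.variant_id}: risk allele {self.risk_allele!r} is neither "
                f"REF {self.ref_allele!r} nor ALT {self.alt_allele!r}"
            )
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.variant_id}: MAF {self.maf} outside [0, 0.5]")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (one adjusted model)."""

    terms: list[str]
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    n_used: int
    converged: bool
    n_iterations: int
    separation: bool = False

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self.terms.index(term)])


@dataclass
class EffectEstimate:
    """Odds ratio with CI and p-value(s) for one contrast."""

    label: str
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    p_permutation: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError(
                f"{self.label}: OR {self.or_point} outside CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )


def genotype_columns(cohort: pd.DataFrame) -> list[str]:
    """Columns of the cohort frame that hold variant dosages."""
    return [c for c in cohort.columns if c not in PHENOTYPE_COLUMNS]


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the cohort-table invariants; raise ``ValueError`` on violation."""
    if cohort["sample_id"].duplicated().any():
        dups = cohort.loc[cohort["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id values: {dups[:5]}")
    if not cohort["status"].isin([0, 1]).all():
        raise ValueError("status must be coded 0 (control) / 1 (case)")
    for col in genotype_columns(cohort):
        vals = cohort[col].dropna()
        if not vals.isin([0, 1, 2]).all():
            bad = sorted(set(vals) - {0, 1, 2})
            raise ValueError(f"{col}: dosages outside {{0,1,2}}: {bad[:5]}")
    for col, levels in VOCABULARY.items():
        if col not in cohort.columns:
            continue
        vals = cohort[col].dropna()
        unknown = sorted(set(vals) - set(levels))
        if unknown:
            raise ValueError(f"{col}: unknown levels {unknown}")
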