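"""Per-variant quality control: counts, MAF, call rate, HWE, pairwise LD.

HWE is tested in controls with a 1-df chi-square goodness of fit against
p^2 / 2pq / q^2 expectations, and the inferential p-value comes from a
permutation scheme that pools the 2n observed alleles and re-pairs them
at random into n genotypes (conditional on the allele counts).  No
continuity correction is applied to the chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import genotype_columns


class MonomorphicVariantError(ValueError):
    """Raised when a test is undefined because only one allele is observed."""


@dataclass
class HweResult:
    variant_id: str
    n_AA: int
    n_Aa: int
    n_aa: int
    chi2: float
    p_asymptotic: float
    p_permutation: Optional[float] = None
    n_permutations: int = 0


def genotype_counts(dosages) -> tuple[int, int, int, int]:
    """Tally (n_AA, n_Aa, n_aa, n_missing) from 0/1/2/NaN dosages.

    AA is the REF homozygote (dosage 0), aa the ALT homozygote (dosage 2).
    """
    arr = np.asarray(dosages, dtype=float)
    n_missing = int(np.isnan(arr).sum())
    called = arr[~np.isnan(arr)]
    return (int((called == 0).sum()), int((called == 1).sum()),
            int((called == 2).sum()), n_missing)


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int,
             variant_id: str = "") -> HweResult:
    """Asymptotic 1-df HWE goodness-of-fit test from genotype counts."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no called genotypes")
    p = (2 * n_AA + n_Aa) / (2 * n)  # frequency of the A allele
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        raise MonomorphicVariantError(
            f"{variant_id or 'variant'}: only one allele observed; HWE not tested")
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_val = float(stats.chi2.sf(chi2, df=1))
    return HweResult(variant_id, n_AA, n_Aa, n_aa, chi2, p_val)


def hwe_permutation_p(n_AA: int, n_Aa: int, n_aa: int, B: int = 1000,
                      seed: int = 0, variant_id: str = "") -> HweResult:
    """HWE test with a permutation p-value by random allele re-pairing.

    The 2n observed alleles are pooled and re-paired into n genotypes B
    times; p = (1 + #{chi2_perm >= chi2_obs}) / (B + 1), so p >= 1/(B+1).
    """
    result = hwe_chi2(n_AA, n_Aa, n_aa, variant_id)
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    rng = np.random.default_rng(seed)
    # Conditional on the allele counts, the chi-square of a re-paired
    # dataset is a function of its heterozygote count alone:
    #   n_AA = (n_A - h)/2, n_aa = (n_a - h)/2.
    # Work with the minor-allele indicator so the procedure (and hence the
    # Monte-Carlo p under a fixed seed) is invariant to allele relabeling.
    n_minor = min(n_A, 2 * n - n_A)
    alleles = np.zeros(2 * n, dtype=np.int8)
    alleles[:n_minor] = 1
    p_hat = n_A / (2 * n)
    q_hat = 1.0 - p_hat
    expected = np.array([n * p_hat * p_hat, 2 * n * p_hat * q_hat,
                         n * q_hat * q_hat])
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(alleles)
        h = int(((perm[:n] + perm[n:]) == 1).sum())
        obs = np.array([(n_A - h) / 2, h, (2 * n - n_A - h) / 2])
        chi2_perm = ((obs - expected) ** 2 / expected).sum()
        if chi2_perm >= result.chi2 - 1e-12:
            exceed += 1
    result.p_permutation = (1 + exceed) / (B + 1)
    result.n_permutations = B
    return result


def pairwise_r2(dosages_a, dosages_b) -> float:
    """Composite LD: squared Pearson correlation of the two dosage vectors
    over complete pairs (phase-free)."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least 2 complete pairs")
    if np.var(a) == 0 or np.var(b) == 0:
        raise MonomorphicVariantError("zero dosage variance; r2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def qc_report(cohort: pd.DataFrame, B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-variant QC table: genotype counts in cases/controls, MAF, call
    rate, and the control-group HWE asymptotic and permutation p-values."""
    rows = []
    controls = cohort[cohort["status"] == 0]
    cases = cohort[cohort["status"] == 1]
    rng = np.random.default_rng(seed)
    for vid in genotype_columns(cohort):
        ca = genotype_counts(cases[vid])
        co = genotype_counts(controls[vid])
        called = cohort[vid].dropna()
        alt_freq = called.sum() / (2 * len(called)) if len(called) else np.nan
        maf = min(alt_freq, 1 - alt_freq)
        row = {
            "variant": vid,
            "cases_AA": ca[0], "cases_Aa": ca[1], "cases_aa": ca[2],
            "controls_AA": co[0], "controls_Aa": co[1], "controls_aa": co[2],
            "maf": maf,
            "call_rate": cohort[vid].notna().mean(),
        }
        try:
            res = hwe_permutation_p(co[0], co[1], co[2], B=B,
                                    seed=int(rng.integers(2**31)),
                                    variant_id=vid)
            row.update(hwe_chi2=res.chi2, hwe_p=res.p_asymptotic,
                       hwe_p_permutation=res.p_permutation)
        except MonomorphicVariantError:
            row.update(hwe_chi2=np.nan, hwe_p=np.nan, hwe_p_permutation=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
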