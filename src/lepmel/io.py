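"""Reading genotypes and phenotypes, joining the analysis frame, writing tables.

Genotypes are ingested as ALT-allele dosage regardless of which allele is
the designated risk allele; orientation happens in :mod:`lepmel.grs`.
Supported genotype formats: VCF 4.x (GT field; phased and unphased
separators treated identically; any half-missing call is missing) and a
wide dosage TSV (first column ``sample_id``, one column per variant with
values 0/1/2/NA).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    NULLABLE_COLUMNS,
    PHENOTYPE_COLUMNS,
    STATUS_CODES,
    VOCABULARY,
    VariantInfo,
    genotype_columns,
)


class ParseError(ValueError):
    pass


def read_genotypes(path: str, format: str = "vcf"):
    """Read a genotype file into a dosage matrix plus per-variant metadata.

    Returns ``(dosages, variants)`` where ``dosages`` is a DataFrame indexed
    by ``sample_id`` with one float column per variant (NaN = missing call)
    and ``variants`` is a list of :class:`VariantInfo`.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str):
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    variants: list[VariantInfo] = []
    columns: dict[str, np.ndarray] = {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(
                f"multi-allelic record rejected: {rec.ID or rec.POS} "
                f"(ALT alleles: {rec.ALT})"
            )
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        # genotypes: [allele_a, allele_b, phased]; -1 marks a missing allele,
        # so any half-missing GT becomes a missing dosage
        gts = np.asarray(rec.genotypes, dtype=float)[:, :2]
        dosage = gts.sum(axis=1)
        dosage[(gts < 0).any(axis=1)] = np.nan
        n_called = int(np.sum(~np.isnan(dosage)))
        if n_called:
            alt_freq = float(np.nansum(dosage)) / (2 * n_called)
        else:
            alt_freq = np.nan
        maf = min(alt_freq, 1 - alt_freq) if n_called else None
        variants.append(
            VariantInfo(
                variant_id=vid,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                maf=maf,
                call_rate=n_called / len(samples) if samples else 0.0,
            )
        )
        columns[vid] = dosage
    dosages = pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"))
    return dosages, variants


def _read_dosage_tsv(path: str):
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"])
    first = df.columns[0]
    if first != "sample_id":
        raise ParseError(f"first column must be sample_id, got {first!r}")
    if df["sample_id"].duplicated().any():
        raise ParseError("duplicate sample_id in dosage file")
    df = df.set_index("sample_id")
    for i, col in enumerate(df.columns):
        vals = df[col].dropna()
        if not vals.isin([0, 1, 2]).all():
            bad_rows = df.index[~df[col].isna() & ~df[col].isin([0, 1, 2])]
            raise ParseError(
                f"column {col!r}: dosage outside {{0,1,2,NA}} at sample "
                f"{bad_rows[0]!r} (line {df.index.get_loc(bad_rows[0]) + 2})"
            )
    variants = [
        VariantInfo(variant_id=c, ref_allele="N", alt_allele="N'",
                    call_rate=float(df[c].notna().mean()))
        for c in df.columns
    ]
    return df.astype(float), variants


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read the per-sample phenotype/covariate TSV into a cohort frame.

    Validates every categorical column against the declared vocabulary and
    codes ``status`` to 0/1.  Missing lifestyle values are retained as NaN;
    the sample stays in the table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[""])
    missing_cols = [c for c in ("sample_id", "status") if c not in df.columns]
    if missing_cols:
        raise ParseError(f"phenotype file missing required columns: {missing_cols}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"duplicate sample_id values: {dups[:5]}")
    if df["status"].isna().any():
        raise ParseError("missing status values")
    bad_status = sorted(set(df["status"]) - set(STATUS_CODES))
    if bad_status:
        raise ParseError(f"uncodable status values: {bad_status}")
    df["status"] = df["status"].map(STATUS_CODES).astype(np.int8)
    for col, levels in VOCABULARY.items():
        if col not in df.columns:
            continue
        vals = df[col]
        if col not in NULLABLE_COLUMNS and vals.isna().any():
            raise ParseError(f"column {col!r} has missing values but is not nullable")
        unknown = sorted(set(vals.dropna()) - set(levels))
        if unknown:
            raise ParseError(f"column {col!r}: unknown levels {unknown}")
    return df


def join_cohort(phenotypes: pd.DataFrame, dosages: pd.DataFrame,
                variants: Iterable[VariantInfo] | None = None):
    """Inner-join phenotypes with the dosage matrix on ``sample_id``.

    Returns ``(cohort, report)`` where ``report`` counts samples dropped
    from each side.  Raises on an empty intersection.
    """
    pheno_ids = set(phenotypes["sample_id"])
    geno_ids = set(dosages.index)
    common = pheno_ids & geno_ids
    if not common:
        raise ValueError("no overlapping sample ids between phenotypes and genotypes")
    report = {
        "n_joined": len(common),
        "dropped_phenotype_only": len(pheno_ids - geno_ids),
        "dropped_genotype_only": len(geno_ids - pheno_ids),
    }
    cohort = phenotypes.merge(
        dosages, left_on="sample_id", right_index=True, how="inner"
    ).reset_index(drop=True)
    return cohort, report


def write_cohort(cohort: pd.DataFrame, path: str) -> None:
    """Write the joined cohort to TSV, dosages as 0/1/2/NA (round-trip safe)."""
    out = cohort.copy()
    for col in genotype_columns(out):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort(path: str) -> pd.DataFrame:
    """Read back a cohort TSV written by :func:`write_cohort`."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[""])
    df["status"] = df["status"].astype(np.int8)
    for col in genotype_columns(df):
        df[col] = pd.to_numeric(df[col].replace("NA", np.nan))
    return df


def write_vcf(dosages: pd.DataFrame, variants: Iterable[VariantInfo],
              path: str) -> None:
    """Write ALT-dosage columns as a minimal VCF 4.2 (GT only).

    Loci are abstract: placed on chromosome 1 at consecutive positions.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = list(dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos, var in enumerate(variants, start=1):
            col = dosages[var.variant_id]
            gts = "\t".join(
                "./." if pd.isna(v) else gt_map[int(v)] for v in col)
            fh.write(f"1\t{pos * 1000}\t{var.variant_id}\t{var.ref_allele}\t"
                     f"{var.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def write_phenotypes(cohort: pd.DataFrame, path: str) -> None:
    """Write the phenotype columns (no genotypes) as a TSV readable by
    :func:`read_phenotypes`; status written as case/control."""
    pheno = cohort[[c for c in PHENOTYPE_COLUMNS if c in cohort.columns]].copy()
    pheno["status"] = pheno["status"].map({1: "case", 0: "control"})
    pheno.to_csv(path, sep="\t", index=False, na_rep="")


def write_table(df: pd.DataFrame, path: str, float_format: str = "%.6g") -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
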