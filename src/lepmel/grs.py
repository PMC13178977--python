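"""Genetic risk scores: construction, categorization, association, stratification.

The unweighted GRS is the sum of risk-allele counts across the selected
variants; the weighted GRS weights each count by the variant's additive
log-odds coefficient.  Samples missing any component variant carry no
score (flagged incomplete).  Scores are cut into low/medium/high at the
first and third quartiles with whole-value snapping: a distinct score
value v is "low" when the empirical CDF F(v) <= 0.25, "high" when
F(v) > 0.75, else "medium" — so categories are always unions of score
values and the realized cutpoints are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    build_design,
    fit_logistic,
    wald_effect,
)
from .datamodel import ADJUSTMENT_COVARIATES, EffectEstimate, VariantInfo


@dataclass
class GrsWeights:
    """Per-variant risk alleles and additive-model log-odds weights."""

    variant_ids: list[str]
    risk_alleles: dict[str, str]
    betas: dict[str, float]

    def __post_init__(self) -> None:
        for vid in self.variant_ids:
            if not np.isfinite(self.betas[vid]):
                raise ValueError(f"{vid}: non-finite beta")


def orient_to_risk(dosage, variant: VariantInfo):
    """ALT dosage -> risk-allele dosage (2 - dosage when REF is the risk
    allele); missing propagates."""
    d = np.asarray(dosage, dtype=float)
    if variant.risk_allele is None:
        raise ValueError(f"{variant.variant_id}: no designated risk allele")
    if variant.risk_allele == variant.alt_allele:
        return d
    return 2.0 - d


def risk_dosage_frame(cohort: pd.DataFrame,
                      variants: Sequence[VariantInfo]) -> pd.DataFrame:
    """Risk-oriented dosage columns for the given variants."""
    return pd.DataFrame(
        {v.variant_id: orient_to_risk(cohort[v.variant_id], v)
         for v in variants}, index=cohort.index)


def compute_grs(risk_dosages: pd.DataFrame, weights: GrsWeights) -> pd.DataFrame:
    """Unweighted and weighted GRS per sample over complete profiles.

    Returns a frame with columns ``unweighted``, ``weighted``, ``complete``;
    incomplete profiles (any component dosage missing) carry NaN scores.
    """
    missing_vars = [v for v in weights.variant_ids
                    if v not in risk_dosages.columns]
    if len(missing_vars) == len(weights.variant_ids):
        raise ValueError("no GRS component variants present in the cohort")
    if missing_vars:
        raise ValueError(f"GRS component variants absent: {missing_vars}")
    comp = risk_dosages[weights.variant_ids]
    complete = comp.notna().all(axis=1)
    unweighted = comp.sum(axis=1).where(complete)
    beta_vec = np.array([weights.betas[v] for v in weights.variant_ids])
    weighted = (comp * beta_vec).sum(axis=1).where(complete)
    return pd.DataFrame({"unweighted": unweighted, "weighted": weighted,
                         "complete": complete})


def estimate_weights(cohort: pd.DataFrame, risk_dosages: pd.DataFrame,
                     variant_ids: Sequence[str],
                     risk_alleles: dict[str, str],
                     covariates: Sequence[str] = ADJUSTMENT_COVARIATES
                     ) -> GrsWeights:
    """Default weights: each variant's adjusted additive-model log-odds
    coefficient re-estimated on the current cohort."""
    betas = {}
    for vid in variant_ids:
        extra = pd.DataFrame({"additive": np.asarray(risk_dosages[vid],
                                                     dtype=float)})
        X, y, terms, _ = build_design(cohort, covariates, extra=extra)
        fit = fit_logistic(X, y, terms)
        betas[vid] = fit.coef("additive")
    return GrsWeights(list(variant_ids), dict(risk_alleles), betas)


def categorize(scores, explicit_cutpoints: Optional[tuple[float, float]] = None
               ) -> tuple[pd.Series, dict]:
    """Low/medium/high GRS categories with whole-value quartile snapping.

    With ``explicit_cutpoints`` (c1, c2): low = score <= c1, high = score
    > c2.  Otherwise a distinct value v is low when F(v) <= 0.25 and high
    when F(v) > 0.75 (F = empirical CDF of the non-missing scores), so the
    bins are unions of realized score values.  Reports the realized
    boundaries {low_max, medium_max}.
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    obs = s.dropna()
    if len(obs) < 4:
        raise ValueError("need at least 4 non-missing scores")
    if explicit_cutpoints is not None:
        c1, c2 = explicit_cutpoints
    else:
        values, counts = np.unique(obs.to_numpy(), return_counts=True)
        cdf = np.cumsum(counts) / counts.sum()
        low_vals = values[cdf <= 0.25]
        med_vals = values[(cdf > 0.25) & (cdf <= 0.75)]
        if len(low_vals) == 0 or len(med_vals) == 0 or len(values) == (
                len(low_vals) + len(med_vals)):
            raise ValueError(
                "degenerate score distribution (empty low/medium/high bin); "
                "supply explicit cutpoints")
        c1 = float(low_vals[-1])
        c2 = float(med_vals[-1])
    cat = pd.Series(pd.NA, index=s.index, dtype="object")
    cat[s <= c1] = "low"
    cat[(s > c1) & (s <= c2)] = "medium"
    cat[s > c2] = "high"
    return cat, {"low_max": c1, "medium_max": c2}


def grs_association(cohort: pd.DataFrame, scores: pd.Series,
                    categories: pd.Series,
                    covariates: Sequence[str] = ADJUSTMENT_COVARIATES,
                    per_unit: float = 1.0) -> pd.DataFrame:
    """Adjusted GRS-obesity association table.

    Contrasts: medium and high vs low; high vs low/medium; per
    ``per_unit`` score increment; plus the trend p from the model with
    category entered as ordinal 0/1/2.
    """
    work = cohort.copy()
    work["_score"] = np.asarray(scores, dtype=float)
    work["_cat"] = categories.to_numpy()
    work = work[work["_score"].notna()]
    rows = []

    cat_num = work["_cat"].map({"low": 0.0, "medium": 1.0, "high": 2.0})
    for level in ("medium", "high"):
        if not (work["_cat"] == level).any():
            raise ValueError(f"empty GRS category {level!r}")
    extra = pd.DataFrame({"medium": (work["_cat"] == "medium").astype(float),
                          "high": (work["_cat"] == "high").astype(float)},
                         index=work.index)
    X, y, terms, _ = build_design(work, covariates, extra=extra)
    fit3 = fit_logistic(X, y, terms)
    for level in ("medium", "high"):
        eff = wald_effect(fit3, level, label=f"{level} vs low")
        rows.append(_row(eff))

    extra = pd.DataFrame({"high": (work["_cat"] == "high").astype(float)},
                         index=work.index)
    X, y, terms, _ = build_design(work, covariates, extra=extra)
    eff = wald_effect(fit_logistic(X, y, terms), "high",
                      label="high vs low/medium")
    rows.append(_row(eff))

    extra = pd.DataFrame({"per_unit": work["_score"] / per_unit},
                         index=work.index)
    X, y, terms, _ = build_design(work, covariates, extra=extra)
    eff = wald_effect(fit_logistic(X, y, terms), "per_unit",
                      label=f"per {per_unit:g} score increment")
    rows.append(_row(eff))

    extra = pd.DataFrame({"trend": cat_num}, index=work.index)
    X, y, terms, _ = build_design(work, covariates, extra=extra)
    p_trend = wald_effect(fit_logistic(X, y, terms), "trend").p
    out = pd.DataFrame(rows)
    out["p_trend"] = p_trend
    return out


def _row(eff: EffectEstimate) -> dict:
    return {"contrast": eff.label, "odds_ratio": eff.or_point,
            "ci_low": eff.ci_low, "ci_high": eff.ci_high, "p": eff.p}


def heterogeneity_z(b1: float, se1: float, b2: float, se2: float
                    ) -> tuple[float, float]:
    """Z test for equality of two independent regression coefficients."""
    z = (b1 - b2) / np.sqrt(se1 ** 2 + se2 ** 2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def cochran_q(betas: Sequence[float], ses: Sequence[float]
              ) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic across strata."""
    b = np.asarray(betas, dtype=float)
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(b) - 1
    return q, df, float(stats.chi2.sf(q, df))


def stratified_grs(cohort: pd.DataFrame, scores: pd.Series,
                   categories: pd.Series, stratifier: str,
                   covariates: Sequence[str] = ADJUSTMENT_COVARIATES
                   ) -> pd.DataFrame:
    """High-vs-low/medium adjusted OR per stratum with heterogeneity tests.

    The stratifier is dropped from the adjustment set; strata with a
    single status are skipped with a warning row.  Pairwise Z compares
    each stratum to the first; an overall Cochran-Q is attached when >2
    strata are fit.
    """
    adj = [c for c in covariates if c != stratifier]
    work = cohort.copy()
    work["_score"] = np.asarray(scores, dtype=float)
    work["_cat"] = categories.to_numpy()
    work = work[work["_score"].notna()]
    rows, fits = [], []
    for level in pd.unique(work[stratifier].dropna()):
        sub = work[work[stratifier] == level]
        if sub["status"].nunique() < 2:
            rows.append({"stratum": level, "skipped": True})
            continue
        extra = pd.DataFrame({"high": (sub["_cat"] == "high").astype(float)},
                             index=sub.index)
        X, y, terms, _ = build_design(sub, adj, extra=extra)
        fit = fit_logistic(X, y, terms)
        eff = wald_effect(fit, "high")
        rows.append({"stratum": level, "skipped": False,
                     "n_cases": int(sub["status"].sum()),
                     "n_controls": int((sub["status"] == 0).sum()),
                     "odds_ratio": eff.or_point, "ci_low": eff.ci_low,
                     "ci_high": eff.ci_high, "p": eff.p,
                     "beta": fit.coef("high"), "se": fit.se("high")})
        fits.append((fit.coef("high"), fit.se("high")))
    out = pd.DataFrame(rows)
    fitted = out[~out["skipped"]] if "skipped" in out else out
    if len(fits) >= 2:
        b0, s0 = fits[0]
        z_col, p_col = [], []
        for i, (b, s) in enumerate(fits):
            if i == 0:
                z_col.append(np.nan)
                p_col.append(np.nan)
            else:
                z, p = heterogeneity_z(b0, s0, b, s)
                z_col.append(z)
                p_col.append(p)
        out.loc[~out["skipped"], "het_z_vs_first"] = z_col
        out.loc[~out["skipped"], "het_p_vs_first"] = p_col
        if len(fits) > 2:
            q, df, p = cochran_q([b for b, _ in fits], [s for _, s in fits])
            out["cochran_q"] = q
            out["cochran_q_p"] = p
    return out
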