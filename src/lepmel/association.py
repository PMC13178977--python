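"""Case-control comparisons and adjusted logistic association models.

The logistic fitter is maximum likelihood via iteratively reweighted
least squares (IRLS) with Wald standard errors from the inverse observed
information.  Genetic effects enter under four codings (genotypic,
dominant, recessive, additive) on the risk-allele orientation; the
adjustment set is the categorical covariates age group, sex, maternal
and paternal education, and household income.  Multiple-testing
correction is a per-test permutation p-value obtained by permuting the
genotype column against the (status, covariates) rows, which keeps the
status-covariate structure intact under the null of no genetic effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ADJUSTMENT_COVARIATES, EffectEstimate, LogisticFit


@dataclass
class Contingency2x2:
    """Cell counts: a=exposed case, b=unexposed case, c=exposed control,
    d=unexposed control."""

    a: int
    b: int
    c: int
    d: int


class SeparationWarning(UserWarning):
    pass


# ---------------------------------------------------------------- descriptive

def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence on an r x c count table
    (no continuity correction)."""
    obs = np.asarray(table, dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected count of zero")
    return float(chi2), int(df), float(p)


def two_sample_t(values_case, values_control, welch: bool = False
                 ) -> tuple[float, float]:
    """Two-sample t-test (pooled variance by default, Welch via flag)."""
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(t):
        raise ValueError("zero pooled variance")
    return float(t), float(p)


def crude_or(table: Contingency2x2, alpha: float = 0.05,
             zero_cell_correction: bool = False,
             label: str = "") -> EffectEstimate:
    """Crude odds ratio with the Woolf (log-normal) confidence interval."""
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if not zero_cell_correction:
            raise ValueError("zero cell; enable the 0.5 correction or fix counts")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(log_or / se))
    return EffectEstimate(label=label, or_point=float(np.exp(log_or)),
                          ci_low=float(np.exp(log_or - z * se)),
                          ci_high=float(np.exp(log_or + z * se)), p=float(p))


# ---------------------------------------------------------------- genetic coding

GENETIC_MODELS = ("genotypic", "dominant", "recessive", "additive")


def code_genotype(dosage, model: str) -> pd.DataFrame:
    """Design column(s) for a risk-oriented dosage under a genetic model.

    genotypic -> two indicators (heterozygote, risk-homozygote) against the
    non-carrier reference; dominant -> dosage>=1; recessive -> dosage==2;
    additive -> the 0/1/2 count itself.  Missing dosage propagates as NaN
    (rows are excluded at fit time).
    """
    d = pd.Series(np.asarray(dosage, dtype=float))
    if model == "genotypic":
        out = pd.DataFrame({"het": (d == 1).astype(float),
                            "hom": (d == 2).astype(float)})
    elif model == "dominant":
        out = pd.DataFrame({"dominant": (d >= 1).astype(float)})
    elif model == "recessive":
        out = pd.DataFrame({"recessive": (d == 2).astype(float)})
    elif model == "additive":
        out = pd.DataFrame({"additive": d})
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    out[d.isna()] = np.nan
    return out


# ---------------------------------------------------------------- logistic IRLS

def fit_logistic(X: np.ndarray, y: np.ndarray, terms: Sequence[str],
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Logistic regression by IRLS with Wald covariance.

    ``X`` must be full rank and include its own intercept column if one is
    wanted.  Convergence requires max |score| < tol or max coefficient
    change < tol; a coefficient exceeding 15 in absolute value flags
    (quasi-)complete separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if max(np.abs(score).max(), np.abs(delta).max()) < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    with np.errstate(divide="ignore"):
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    separation = bool(np.abs(beta).max() > 15)
    if separation:
        warnings.warn("possible separation: |coefficient| > 15",
                      SeparationWarning, stacklevel=2)
    return LogisticFit(terms=list(terms), params=beta, cov=cov, loglik=ll,
                       n_used=n, converged=converged, n_iterations=it,
                       separation=separation)


def build_design(cohort: pd.DataFrame,
                 covariates: Sequence[str] = ADJUSTMENT_COVARIATES,
                 extra: Optional[pd.DataFrame] = None
                 ) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Assemble (X, y, terms, row_index) for an adjusted logistic model.

    Covariates enter as indicator columns with the first observed level as
    reference; ``extra`` columns (already numeric) are appended after the
    intercept.  Rows with any missing value in the used columns drop out;
    the returned ``row_index`` gives the positional indices kept.
    """
    parts = [pd.Series(1.0, index=cohort.index, name="intercept")]
    if extra is not None:
        for col in extra.columns:
            parts.append(pd.Series(np.asarray(extra[col], dtype=float),
                                   index=cohort.index, name=col))
    for cov in covariates:
        s = cohort[cov]
        levels = list(pd.unique(s.dropna()))
        for level in levels[1:]:
            parts.append(pd.Series((s == level).astype(float).where(s.notna()),
                                   index=cohort.index,
                                   name=f"{cov}[{level}]"))
    design = pd.concat(parts, axis=1)
    keep = design.notna().all(axis=1) & cohort["status"].notna()
    X = design.loc[keep].to_numpy(dtype=float)
    y = cohort.loc[keep, "status"].to_numpy(dtype=float)
    return X, y, list(design.columns), np.flatnonzero(keep.to_numpy())


def wald_effect(fit: LogisticFit, term: str, alpha: float = 0.05,
                label: str = "") -> EffectEstimate:
    """OR, Wald CI and two-sided p for one model term."""
    b = fit.coef(term)
    se = fit.se(term)
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(b / se))
    return EffectEstimate(label=label or term, or_point=float(np.exp(b)),
                          ci_low=float(np.exp(b - z * se)),
                          ci_high=float(np.exp(b + z * se)), p=float(p))


def adjusted_genotype_fit(cohort: pd.DataFrame, risk_dosage, model: str,
                          covariates: Sequence[str] = ADJUSTMENT_COVARIATES
                          ) -> tuple[LogisticFit, list[str]]:
    """Fit the adjusted model for one variant under one genetic coding.

    Returns the fit plus the genotype term names (the contrasts of
    interest)."""
    coded = code_genotype(risk_dosage, model)
    X, y, terms, _ = build_design(cohort, covariates, extra=coded)
    fit = fit_logistic(X, y, terms)
    return fit, list(coded.columns)


def permutation_p_association(cohort: pd.DataFrame, risk_dosage, model: str,
                              term: str, B: int = 1000, seed: int = 0,
                              covariates: Sequence[str] = ADJUSTMENT_COVARIATES
                              ) -> float:
    """Per-test permutation p for one genotype term's Wald z.

    The genotype column is permuted against the (status, covariates) rows
    B times; each permuted dataset is refit and the term's |z| recorded;
    p = (1 + #{|z_perm| >= |z_obs|}) / (B + 1).  Non-converged permuted
    fits are dropped from the denominator (warned above 5%).
    """
    rng = np.random.default_rng(seed)
    dosage = np.asarray(risk_dosage, dtype=float)
    coded = code_genotype(dosage, model)
    X, y, terms, rows = build_design(cohort, covariates, extra=coded)
    fit = fit_logistic(X, y, terms)
    if not fit.converged:
        raise ValueError("unpermuted fit did not converge")
    j = terms.index(term)
    z_obs = abs(fit.params[j] / np.sqrt(fit.cov[j, j]))

    geno_cols = [terms.index(c) for c in coded.columns]
    base_geno = X[:, geno_cols].copy()
    exceed = 0
    used = 0
    failed = 0
    for _ in range(B):
        perm = rng.permutation(len(X))
        Xp = X.copy()
        Xp[:, geno_cols] = base_geno[perm]
        pf = fit_logistic(Xp, y, terms)
        if not pf.converged:
            failed += 1
            continue
        zj = abs(pf.params[j] / np.sqrt(pf.cov[j, j]))
        used += 1
        if zj >= z_obs - 1e-12:
            exceed += 1
    if failed > 0.05 * B:
        warnings.warn(f"{failed}/{B} permuted fits failed to converge",
                      stacklevel=2)
    return (1 + exceed) / (used + 1)


def association_report(cohort: pd.DataFrame, variant_ids: Sequence[str],
                       risk_dosages: pd.DataFrame,
                       B: int = 1000, seed: int = 0,
                       models: Sequence[str] = GENETIC_MODELS,
                       covariates: Sequence[str] = ADJUSTMENT_COVARIATES
                       ) -> pd.DataFrame:
    """Per-variant association table under the four genetic codings:
    crude and adjusted OR/CI/p plus the permutation-corrected p."""
    rng = np.random.default_rng(seed)
    rows = []
    y_all = cohort["status"].to_numpy()
    for vid in variant_ids:
        dosage = np.asarray(risk_dosages[vid], dtype=float)
        for model in models:
            coded = code_genotype(dosage, model)
            fit, geno_terms = adjusted_genotype_fit(
                cohort, dosage, model, covariates)
            for term in geno_terms:
                # crude OR from the marginal 2x2 (or per-allele crude fit)
                crude = _crude_for_term(y_all, dosage, model, term)
                adj = wald_effect(fit, term)
                p_perm = permutation_p_association(
                    cohort, dosage, model, term, B=B,
                    seed=int(rng.integers(2**31)), covariates=covariates)
                rows.append({
                    "variant": vid, "model": model, "contrast": term,
                    "crude_or": crude.or_point, "crude_ci_low": crude.ci_low,
                    "crude_ci_high": crude.ci_high, "crude_p": crude.p,
                    "adj_or": adj.or_point, "adj_ci_low": adj.ci_low,
                    "adj_ci_high": adj.ci_high, "adj_p": adj.p,
                    "p_permutation": p_perm, "n_used": fit.n_used,
                })
    return pd.DataFrame(rows)


def _crude_for_term(y: np.ndarray, dosage: np.ndarray, model: str,
                    term: str) -> EffectEstimate:
    keep = ~np.isnan(dosage)
    yk, dk = y[keep], dosage[keep]
    if model == "additive":
        X = np.column_stack([np.ones(keep.sum()), dk])
        fit = fit_logistic(X, yk, ["intercept", "additive"])
        return wald_effect(fit, "additive")
    if model == "genotypic":
        exposed = dk == (1 if term == "het" else 2)
        ref = dk == 0
        sel = exposed | ref
        yk, exposed = yk[sel], exposed[sel]
    elif model == "dominant":
        exposed = dk >= 1
    else:  # recessive
        exposed = dk == 2
    tab = Contingency2x2(int((yk[exposed] == 1).sum()),
                         int((yk[~exposed] == 1).sum()),
                         int((yk[exposed] == 0).sum()),
                         int((yk[~exposed] == 0).sum()))
    return crude_or(tab, label=term)
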