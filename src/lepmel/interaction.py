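"""Gene-lifestyle crossover interaction on the additive and multiplicative scales.

The crossover design codes the four G x E cells (binary GRS x binary
lifestyle exposure) as three indicators against the doubly-unexposed
reference (low/medium GRS with the adequate exposure level) inside one
covariate-adjusted logistic model.  From the three adjusted odds ratios:

    RERI = OR11 - OR10 - OR01 + 1   (0 under additivity of joint effects)
    AP   = RERI / OR11              (share of the joint effect due to interaction)
    IOR  = OR11 / (OR10 * OR01)     (1 under multiplicativity)

Confidence intervals come from a percentile bootstrap stratified by
case-control status, refitting the adjusted crossover model per resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import build_design, fit_logistic, wald_effect
from .datamodel import ADJUSTMENT_COVARIATES, EffectEstimate


def reri(or11: float, or10: float, or01: float) -> float:
    """Relative excess risk of interaction: OR11 - OR10 - OR01 + 1."""
    if min(or11, or10, or01) <= 0:
        raise ValueError("odds ratios must be positive")
    return or11 - or10 - or01 + 1.0


def ap(reri_value: float, or11: float) -> float:
    """Attributable proportion of interaction: RERI / OR11."""
    if or11 <= 0:
        raise ValueError("OR11 must be positive")
    return reri_value / or11


def ior(or11: float, or10: float, or01: float) -> float:
    """Interaction odds ratio: OR11 / (OR10 * OR01)."""
    if min(or11, or10, or01) <= 0:
        raise ValueError("odds ratios must be positive")
    return or11 / (or10 * or01)


@dataclass
class InteractionResult:
    grs_label: str
    exposure_label: str
    cell_counts: pd.DataFrame          # cases/controls per G x E cell
    or10: EffectEstimate               # G high, E adequate
    or01: EffectEstimate               # G low/medium, E inadequate
    or11: EffectEstimate               # G high, E inadequate
    reri: float
    ap: float
    ior: float
    reri_ci: Optional[tuple[float, float]] = None
    ap_ci: Optional[tuple[float, float]] = None
    ior_ci: Optional[tuple[float, float]] = None
    n_bootstrap: int = 0
    n_dropped: int = 0
    seed: Optional[int] = None

    @property
    def significant(self) -> dict[str, bool]:
        """CI-exclusion flags: RERI/AP vs 0, IOR vs 1."""
        out = {}
        if self.reri_ci:
            out["reri"] = not (self.reri_ci[0] <= 0 <= self.reri_ci[1])
        if self.ap_ci:
            out["ap"] = not (self.ap_ci[0] <= 0 <= self.ap_ci[1])
        if self.ior_ci:
            out["ior"] = not (self.ior_ci[0] <= 1 <= self.ior_ci[1])
        return out


def _crossover_fit(work: pd.DataFrame, covariates: Sequence[str]):
    extra = pd.DataFrame({
        "g1e0": ((work["_g"] == 1) & (work["_e"] == 0)).astype(float),
        "g0e1": ((work["_g"] == 0) & (work["_e"] == 1)).astype(float),
        "g1e1": ((work["_g"] == 1) & (work["_e"] == 1)).astype(float),
    }, index=work.index)
    X, y, terms, _ = build_design(work, covariates, extra=extra)
    return fit_logistic(X, y, terms), terms


def crossover_table(cohort: pd.DataFrame, grs_high: pd.Series,
                    exposure: pd.Series,
                    covariates: Sequence[str] = ADJUSTMENT_COVARIATES,
                    grs_label: str = "GRS", exposure_label: str = "exposure"
                    ) -> InteractionResult:
    """Cell counts and the three adjusted crossover ORs plus RERI/AP/IOR.

    ``grs_high``: boolean/0-1 (1 = high GRS); ``exposure``: the lifestyle
    column with levels adequate/inadequate (1 = inadequate when numeric).
    Samples missing either factor are excluded.
    """
    work = _prepare(cohort, grs_high, exposure)
    counts = (work.groupby(["_g", "_e"])["status"]
              .agg(n_cases="sum", n_total="count").reset_index())
    counts["n_controls"] = counts["n_total"] - counts["n_cases"]
    if len(counts) < 4 or (counts["n_total"] == 0).any():
        present = set(zip(counts["_g"].astype(int), counts["_e"].astype(int)))
        missing = sorted({(g, e) for g in (0, 1) for e in (0, 1)} - present)
        raise ValueError(f"empty crossover cell(s): {missing}")
    fit, _ = _crossover_fit(work, covariates)
    e10 = wald_effect(fit, "g1e0", label=f"high {grs_label}, adequate")
    e01 = wald_effect(fit, "g0e1", label=f"low/medium {grs_label}, inadequate")
    e11 = wald_effect(fit, "g1e1", label=f"high {grs_label}, inadequate")
    r = reri(e11.or_point, e10.or_point, e01.or_point)
    return InteractionResult(
        grs_label=grs_label, exposure_label=exposure_label,
        cell_counts=counts[["_g", "_e", "n_cases", "n_controls"]],
        or10=e10, or01=e01, or11=e11,
        reri=r, ap=ap(r, e11.or_point),
        ior=ior(e11.or_point, e10.or_point, e01.or_point))


def _prepare(cohort: pd.DataFrame, grs_high, exposure) -> pd.DataFrame:
    work = cohort.copy()
    g = pd.Series(np.asarray(grs_high), index=cohort.index)
    e = pd.Series(np.asarray(exposure, dtype=object), index=cohort.index)
    if e.dropna().isin(["adequate", "inadequate"]).all():
        e = e.map({"adequate": 0, "inadequate": 1})
    work["_g"] = pd.to_numeric(g, errors="coerce")
    work["_e"] = pd.to_numeric(e, errors="coerce")
    work = work[work["_g"].notna() & work["_e"].notna()]
    if work.empty:
        raise ValueError("no samples with both factors observed")
    work["_g"] = work["_g"].astype(int)
    work["_e"] = work["_e"].astype(int)
    return work


def bootstrap_interaction(cohort: pd.DataFrame, grs_high: pd.Series,
                          exposure: pd.Series, B: int = 1000, seed: int = 0,
                          covariates: Sequence[str] = ADJUSTMENT_COVARIATES,
                          stratified: bool = True,
                          grs_label: str = "GRS",
                          exposure_label: str = "exposure"
                          ) -> InteractionResult:
    """Crossover analysis with percentile bootstrap CIs for RERI, AP, IOR.

    Whole samples are resampled with replacement, stratified within the
    case and control groups (preserving the design) unless
    ``stratified=False``; each resample refits the adjusted crossover
    model.  Resamples with empty cells or non-converged fits are dropped
    and counted (warning above 10%).
    """
    result = crossover_table(cohort, grs_high, exposure, covariates,
                             grs_label, exposure_label)
    work = _prepare(cohort, grs_high, exposure).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    case_rows = np.flatnonzero(work["status"] == 1)
    ctrl_rows = np.flatnonzero(work["status"] == 0)
    stats_boot = []
    dropped = 0
    for _ in range(B):
        if stratified:
            rows = np.concatenate([
                rng.choice(case_rows, size=len(case_rows), replace=True),
                rng.choice(ctrl_rows, size=len(ctrl_rows), replace=True)])
        else:
            rows = rng.choice(len(work), size=len(work), replace=True)
        sub = work.iloc[rows].reset_index(drop=True)
        cells = sub.groupby(["_g", "_e"]).size()
        if len(cells) < 4:
            dropped += 1
            continue
        fit, terms = _crossover_fit(sub, covariates)
        if not fit.converged or fit.separation:
            dropped += 1
            continue
        o10, o01, o11 = (float(np.exp(fit.coef(t)))
                         for t in ("g1e0", "g0e1", "g1e1"))
        r = reri(o11, o10, o01)
        stats_boot.append((r, ap(r, o11), ior(o11, o10, o01)))
    if dropped > 0.10 * B:
        import warnings
        warnings.warn(f"{dropped}/{B} bootstrap resamples dropped",
                      stacklevel=2)
    arr = np.asarray(stats_boot)
    lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
    result.reri_ci = (float(lo[0]), float(hi[0]))
    result.ap_ci = (float(lo[1]), float(hi[1]))
    result.ior_ci = (float(lo[2]), float(hi[2]))
    result.n_bootstrap = len(stats_boot)
    result.n_dropped = dropped
    result.seed = seed
    return result


def interaction_report(results: Sequence[InteractionResult]) -> pd.DataFrame:
    """Flat table mirroring the published four-cell layout with the
    interaction measures and their CIs."""
    rows = []
    for res in results:
        counts = res.cell_counts.set_index(["_g", "_e"])
        for (g, e), label, eff in [
            ((0, 0), "low/medium + adequate", None),
            ((0, 1), "low/medium + inadequate", res.or01),
            ((1, 0), "high + adequate", res.or10),
            ((1, 1), "high + inadequate", res.or11),
        ]:
            c = counts.loc[(g, e)]
            rows.append({
                "grs": res.grs_label, "exposure": res.exposure_label,
                "cell": label, "n_cases": int(c["n_cases"]),
                "n_controls": int(c["n_controls"]),
                "adj_or": 1.0 if eff is None else eff.or_point,
                "ci_low": np.nan if eff is None else eff.ci_low,
                "ci_high": np.nan if eff is None else eff.ci_high,
                "reri": res.reri if (g, e) == (1, 1) else np.nan,
                "reri_lo": res.reri_ci[0] if res.reri_ci and (g, e) == (1, 1) else np.nan,
                "reri_hi": res.reri_ci[1] if res.reri_ci and (g, e) == (1, 1) else np.nan,
                "ap": res.ap if (g, e) == (1, 1) else np.nan,
                "ior": res.ior if (g, e) == (1, 1) else np.nan,
            })
    return pd.DataFrame(rows)
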