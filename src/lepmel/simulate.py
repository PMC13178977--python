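"""Synthetic frequency-matched case-control cohorts.

The generator follows the prospective-logistic recipe: simulate a
population pool with genotypes drawn under Hardy-Weinberg equilibrium at
the configured minor-allele frequencies, covariates and lifestyle
exposures drawn from categorical distributions, and disease status drawn
Bernoulli with

    logit P(case) = baseline + sum_v beta_v * risk_dosage_v
                  + lifestyle and interaction terms,

then sample all requested cases and frequency-match controls to them on
sex, age group and school.  Sampling cases and controls from such a pool
leaves the logistic odds ratios of the disease model intact, which is the
property every downstream stage relies on.

Covariates are independent of genotype by default (the emulated study
found no case-control covariate differences); a dependence hook is not
provided beyond lifestyle/interaction effects entering the disease model.
Variants are simulated independently (no linkage disequilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datamodel import VariantInfo, VOCABULARY


@dataclass
class VariantSpec:
    """One simulated biallelic locus.

    ``maf`` is the ALT-allele frequency (kept in (0, 0.5]); ``beta`` the
    per-risk-allele log-odds effect; ``risk_allele`` selects whether ALT
    ("alt") or REF ("ref") carries the effect, exercising the orientation
    logic downstream.  ``hwe_f`` is an inbreeding-like coefficient: the
    heterozygote probability 2pq is scaled by (1 - f).
    """

    id: str
    maf: float
    beta: float = 0.0
    risk_allele: str = "alt"
    hwe_f: float = 0.0
    gene: str = ""
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.id}: maf {self.maf} outside (0, 0.5]")
        if self.risk_allele not in ("ref", "alt"):
            raise ValueError(f"{self.id}: risk_allele must be 'ref' or 'alt'")

    def to_variant_info(self) -> VariantInfo:
        return VariantInfo(
            variant_id=self.id, ref_allele=self.ref, alt_allele=self.alt,
            risk_allele=self.alt if self.risk_allele == "alt" else self.ref,
            maf=self.maf, gene_label=self.gene,
        )


@dataclass
class LifestyleSpec:
    """Binary exposure: probability of the 'inadequate' level and its log-odds."""

    prevalence_inadequate: float
    beta: float = 0.0


@dataclass
class InteractionSpec:
    """Extra log-odds for samples with high genetic burden AND the exposure.

    ``grs_threshold`` applies to the unweighted risk-allele count over
    ``variants`` (all effect variants when empty).
    """

    lifestyle: str
    grs_threshold: int = 3
    variants: tuple[str, ...] = ()
    beta: float = 0.0


def _default_covariates() -> dict[str, dict[str, float]]:
    # margins mirror the emulated study cohort
    return {
        "sex": {"boy": 0.68, "girl": 0.32},
        "age_group": {"7-8": 0.19, "11-14": 0.49, "15-18": 0.32},
        "maternal_edu": {"high_school_or_below": 0.49,
                         "junior_college_or_above": 0.51},
        "paternal_edu": {"high_school_or_below": 0.46,
                         "junior_college_or_above": 0.54},
        "income": {"<5000": 0.30, "5000-9999": 0.37, ">=10000": 0.33},
    }


#: school grade tracks the age band deterministically
_SCHOOL_BY_AGE = {"7-8": "primary-2", "11-14": "junior-1", "15-18": "senior-1"}


@dataclass
class SimulationConfig:
    n_cases: int
    n_controls: int
    variants: list[VariantSpec]
    baseline_log_odds: float = -2.45
    covariates: dict[str, dict[str, float]] = field(default_factory=_default_covariates)
    lifestyle: dict[str, LifestyleSpec] = field(default_factory=dict)
    interactions: list[InteractionSpec] = field(default_factory=list)
    matching_factors: tuple[str, ...] = ("sex", "age_group", "school")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        for dist in self.covariates.values():
            total = sum(dist.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"covariate probabilities sum to {total}, not 1")


def study_like_config(n_cases: int = 1123, n_controls: int = 1231,
                      seed: int = 0) -> SimulationConfig:
    """The default study-like configuration: 12 pathway variants, four with
    the published additive-model effect sizes, lifestyle prevalences near
    the emulated cohort's margins."""
    variants = [
        VariantSpec("rs17782313", 0.22, beta=0.268, gene="MC4R", ref="T", alt="C"),
        VariantSpec("rs12970134", 0.20, beta=0.217, gene="MC4R", ref="G", alt="A"),
        VariantSpec("rs1137101", 0.10, beta=0.110, gene="LEPR", ref="G", alt="A"),
        VariantSpec("rs6713532", 0.25, beta=0.044, gene="POMC", ref="C", alt="T"),
        VariantSpec("rs8087522", 0.30, gene="MC4R", ref="G", alt="A"),
        VariantSpec("rs1349419", 0.35, gene="LEP", ref="T", alt="C"),
        VariantSpec("rs2167270", 0.40, gene="LEP", ref="G", alt="A"),
        VariantSpec("rs1137100", 0.15, gene="LEPR", ref="A", alt="G"),
        VariantSpec("rs6713532b", 0.45, gene="POMC", ref="C", alt="G"),
        VariantSpec("rs16141", 0.25, gene="NPY", ref="T", alt="C"),
        VariantSpec("rs3746619", 0.12, gene="MC3R", ref="C", alt="A"),
        VariantSpec("rs3827103", 0.18, gene="MC3R", ref="G", alt="A"),
    ]
    lifestyle = {
        "physical_activity": LifestyleSpec(prevalence_inadequate=0.86),
        "sleep": LifestyleSpec(prevalence_inadequate=0.80),
    }
    return SimulationConfig(n_cases=n_cases, n_controls=n_controls,
                            variants=variants, lifestyle=lifestyle, seed=seed)


def _risk_dosage(dosage: np.ndarray, spec: VariantSpec) -> np.ndarray:
    return dosage if spec.risk_allele == "alt" else 2.0 - dosage


def simulate_population(config: SimulationConfig, n_pool: int,
                        rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw a population pool with latent disease probability and status.

    Genotype probabilities per locus are (p0, p1, p2) for ALT dosage with
    p1 = 2pq(1-f); f>0 removes heterozygotes symmetrically into both
    homozygote classes (a classic inbreeding-style HWE departure).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool = pd.DataFrame({"sample_id": [f"S{i:06d}" for i in range(n_pool)]})

    for col, dist in config.covariates.items():
        levels = list(dist)
        pool[col] = rng.choice(levels, size=n_pool, p=list(dist.values()))
    pool["school"] = pool["age_group"].map(_SCHOOL_BY_AGE)

    logit = np.full(n_pool, config.baseline_log_odds)
    risk_counts = np.zeros(n_pool)
    risk_by_variant: dict[str, np.ndarray] = {}
    for spec in config.variants:
        p = spec.maf
        q = 1.0 - p
        het = 2 * p * q * (1.0 - spec.hwe_f)
        excess = 2 * p * q * spec.hwe_f / 2.0
        probs = np.array([q * q + excess, het, p * p + excess])
        dosage = rng.choice([0.0, 1.0, 2.0], size=n_pool, p=probs / probs.sum())
        pool[spec.id] = dosage
        rd = _risk_dosage(dosage, spec)
        risk_by_variant[spec.id] = rd
        logit += spec.beta * rd
        if spec.beta != 0:
            risk_counts += rd

    for col, spec in config.lifestyle.items():
        inad = rng.random(n_pool) < spec.prevalence_inadequate
        pool[col] = np.where(inad, "inadequate", "adequate")
        logit += spec.beta * inad

    for inter in config.interactions:
        if inter.variants:
            burden = sum(risk_by_variant[v] for v in inter.variants)
        else:
            burden = risk_counts
        exposed = (pool[inter.lifestyle] == "inadequate").to_numpy()
        logit += inter.beta * ((burden >= inter.grs_threshold) & exposed)

    prob = 1.0 / (1.0 + np.exp(-logit))
    pool["disease_prob"] = prob
    pool["status"] = (rng.random(n_pool) < prob).astype(np.int8)

    n_cases_avail = int(pool["status"].sum())
    if n_cases_avail < config.n_cases:
        raise ValueError(
            f"pool yielded {n_cases_avail} cases < requested {config.n_cases}; "
            "increase n_pool or baseline_log_odds"
        )
    return pool


def frequency_match(pool: pd.DataFrame, n_cases: int, n_controls: int,
                    matching_factors: tuple[str, ...],
                    seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Sample cases, then controls whose joint distribution over the
    matching factors matches the cases' (to the achievable cell counts).

    Cell shortfalls on the control side are reallocated proportionally to
    the remaining cells; the report records per-cell targets, achieved
    counts and shortfalls.
    """
    rng = np.random.default_rng(seed)
    cases_pool = pool[pool["status"] == 1]
    controls_pool = pool[pool["status"] == 0]
    if cases_pool.empty or controls_pool.empty:
        raise ValueError("pool must contain both cases and controls")
    if len(cases_pool) < n_cases:
        raise ValueError("not enough cases in pool")

    cases = cases_pool.sample(n=n_cases, random_state=int(rng.integers(2**31)))
    if not matching_factors:
        controls = controls_pool.sample(
            n=min(n_controls, len(controls_pool)),
            random_state=int(rng.integers(2**31)))
        cohort = pd.concat([cases, controls], ignore_index=True)
        return cohort.drop(columns="disease_prob"), {"cells": {}, "shortfall": 0}

    factors = list(matching_factors)

    def keyify(k):
        return k if isinstance(k, tuple) else (k,)

    case_cells = pd.Series(
        {keyify(k): v for k, v in
         cases.groupby(factors, observed=True).size().items()})
    targets = _apportion(case_cells / case_cells.sum() * n_controls)
    ctrl_groups = {keyify(k): g for k, g in
                   controls_pool.groupby(factors, observed=True)}

    taken, shortfalls, used_idx = [], {}, {}
    for cell, want in targets.items():
        grp = ctrl_groups.get(cell)
        n_avail = 0 if grp is None else len(grp)
        take = min(want, n_avail)
        if take:
            samp = grp.sample(n=take, random_state=int(rng.integers(2**31)))
            taken.append(samp)
            used_idx[cell] = samp.index
        if want > n_avail:
            shortfalls[cell] = want - n_avail

    deficit = sum(shortfalls.values())
    if deficit:
        # proportional reallocation across cells with spare controls
        spare = {c: len(g) - len(used_idx.get(c, ()))
                 for c, g in ctrl_groups.items()}
        spare = {c: s for c, s in spare.items() if s > 0}
        spare_total = sum(spare.values())
        extra = _apportion(pd.Series(
            {c: min(deficit, spare_total) * s / spare_total
             for c, s in spare.items()})) if spare_total else {}
        for cell, want in extra.items():
            grp = ctrl_groups[cell].drop(
                index=used_idx.get(cell, pd.Index([])))
            take = min(want, len(grp))
            if take:
                taken.append(grp.sample(
                    n=take, random_state=int(rng.integers(2**31))))
    controls = pd.concat(taken, ignore_index=False) if taken else controls_pool.iloc[:0]
    cohort = pd.concat([cases, controls], ignore_index=True)
    report = {
        "cells": {str(k): int(v) for k, v in targets.items()},
        "shortfall": int(sum(shortfalls.values())),
        "n_controls_selected": int(len(controls)),
    }
    return cohort.drop(columns="disease_prob"), report


def _apportion(weights: pd.Series) -> dict:
    """Largest-remainder rounding of fractional cell targets to integers."""
    floors = np.floor(weights).astype(int)
    remainder = int(round(weights.sum())) - int(floors.sum())
    order = (weights - floors).sort_values(ascending=False).index
    out = floors.to_dict()
    for cell in order[:remainder]:
        out[cell] += 1
    return out


def inject_missingness(cohort: pd.DataFrame, rates: dict[str, float],
                       seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Mask fields missing-completely-at-random at the given per-field rates."""
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    counts = {}
    for col, rate in rates.items():
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"{col}: rate {rate} outside [0, 1)")
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
        counts[col] = int(mask.sum())
    return out, counts


def simulate_cohort(config: SimulationConfig, n_pool: Optional[int] = None,
                    missing_rates: Optional[dict[str, float]] = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Pool simulation + frequency matching (+ optional MCAR masking)."""
    rng = np.random.default_rng(config.seed)
    if n_pool is None:
        # crude sizing: expect enough cases at the configured baseline
        n_pool = max(20000, 20 * config.n_cases)
    pool = simulate_population(config, n_pool, rng)
    cohort, report = frequency_match(
        pool, config.n_cases, config.n_controls, config.matching_factors,
        seed=int(rng.integers(2**31)))
    if missing_rates:
        cohort, masked = inject_missingness(
            cohort, missing_rates, seed=int(rng.integers(2**31)))
        report["masked"] = masked
    cohort = cohort.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    return cohort.reset_index(drop=True), report


def config_to_yaml(config: SimulationConfig, path: str) -> None:
    data = asdict(config)
    data["matching_factors"] = list(config.matching_factors)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_from_yaml(path: str) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["variants"] = [VariantSpec(**v) for v in data["variants"]]
    data["lifestyle"] = {k: LifestyleSpec(**v)
                         for k, v in data.get("lifestyle", {}).items()}
    data["interactions"] = [
        InteractionSpec(**{**d, "variants": tuple(d.get("variants", ()))})
        for d in data.get("interactions", [])
    ]
    data["matching_factors"] = tuple(data.get("matching_factors", ()))
    return SimulationConfig(**data)
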