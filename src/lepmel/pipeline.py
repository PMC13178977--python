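"""Full-pipeline orchestration: QC -> association -> CART -> GRS -> interaction.

One global seed fans out to per-stage seeds through a fixed
``numpy.random.SeedSequence`` derivation, so any stage can be rerun
independently yet reproducibly.  "Important variants" for the GRS stage
are the union of variants significant in single-locus analysis
(permutation p < 0.05 under the dominant or additive model, by default)
and the variants appearing on the path to the highest-risk CART terminal
node.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as lio
from .association import association_report
from .cart import Tree, cross_validate, grow_tree, terminal_node_or
from .datamodel import ADJUSTMENT_COVARIATES, VariantInfo, genotype_columns
from .grs import (
    GrsWeights,
    categorize,
    compute_grs,
    estimate_weights,
    grs_association,
    risk_dosage_frame,
    stratified_grs,
)
from .interaction import bootstrap_interaction, interaction_report
from .qc import qc_report
from .simulate import study_like_config, simulate_cohort

log = logging.getLogger("lepmel")

STAGES = ("qc", "association", "cart", "grs", "interaction")


@dataclass
class PipelineConfig:
    genotypes: str
    phenotypes: str
    genotype_format: str = "vcf"
    risk_alleles: dict[str, str] = field(default_factory=dict)
    gene_labels: dict[str, str] = field(default_factory=dict)
    covariates: list[str] = field(default_factory=lambda: list(ADJUSTMENT_COVARIATES))
    stages: tuple[str, ...] = STAGES
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    seed: int = 0
    output_dir: str = "results"
    cart_min_parent: int = 100
    cart_min_child: int = 50
    significance_alpha: float = 0.05


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seed fan-out (values < 2**31)."""
    ss = np.random.SeedSequence(global_seed)
    children = ss.spawn(len(STAGES))
    return {stage: int(c.generate_state(1)[0] % (2**31))
            for stage, c in zip(STAGES, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; write one TSV per stage plus a run
    log; return the in-memory results bundle."""
    os.makedirs(config.output_dir, exist_ok=True)
    seeds = stage_seeds(config.seed)
    runlog: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": {}}
    bundle: dict = {}

    dosages, variants = lio.read_genotypes(config.genotypes,
                                           config.genotype_format)
    for v in variants:
        if v.variant_id in config.risk_alleles:
            v.risk_allele = config.risk_alleles[v.variant_id]
        if v.variant_id in config.gene_labels:
            v.gene_label = config.gene_labels[v.variant_id]
    phenotypes = lio.read_phenotypes(config.phenotypes)
    cohort, join_report = lio.join_cohort(phenotypes, dosages, variants)
    runlog["join"] = join_report
    runlog["n_cases"] = int(cohort["status"].sum())
    runlog["n_controls"] = int((cohort["status"] == 0).sum())
    bundle["cohort"] = cohort
    bundle["variants"] = variants
    variant_ids = [v.variant_id for v in variants]

    oriented = [v for v in variants if v.risk_allele is not None]
    risk_dos = risk_dosage_frame(cohort, oriented) if oriented else None

    if "qc" in config.stages:
        qc = qc_report(cohort, B=config.n_permutations, seed=seeds["qc"])
        lio.write_table(qc, os.path.join(config.output_dir, "qc_hwe.tsv"))
        bundle["qc"] = qc
        runlog["stages"]["qc"] = {"n_variants": len(qc)}

    assoc = None
    if "association" in config.stages:
        if risk_dos is None:
            raise RuntimeError("association stage requires risk alleles")
        assoc = association_report(
            cohort, [v.variant_id for v in oriented], risk_dos,
            B=config.n_permutations, seed=seeds["association"],
            covariates=config.covariates)
        lio.write_table(assoc, os.path.join(config.output_dir,
                                            "association.tsv"))
        bundle["association"] = assoc
        runlog["stages"]["association"] = {"n_tests": len(assoc)}

    tree: Optional[Tree] = None
    if "cart" in config.stages:
        dmat = cohort[variant_ids].to_numpy(dtype=float)
        y = cohort["status"].to_numpy(dtype=float)
        tree = grow_tree(dmat, y, variant_ids,
                         config.cart_min_parent, config.cart_min_child)
        tree.cv_misclassification = cross_validate(
            dmat, y, variant_ids, k=10, seed=seeds["cart"],
            min_parent=config.cart_min_parent,
            min_child=config.cart_min_child)
        tree.to_json(os.path.join(config.output_dir, "cart_tree.json"))
        node_or = terminal_node_or(tree, cohort, dmat, config.covariates)
        lio.write_table(node_or, os.path.join(config.output_dir,
                                              "cart_nodes.tsv"))
        bundle["cart"] = tree
        bundle["cart_nodes"] = node_or
        runlog["stages"]["cart"] = {
            "n_terminal": len(tree.terminal_ids()),
            "cv_misclassification": tree.cv_misclassification}

    important = important_variants(assoc, tree, cohort,
                                   alpha=config.significance_alpha)
    important = [v for v in important if v in {x.variant_id for x in oriented}]
    runlog["important_variants"] = important

    profiles = None
    if "grs" in config.stages:
        if not important:
            raise RuntimeError("GRS stage: no important variants identified")
        risk_alleles = {v.variant_id: v.risk_allele for v in oriented
                        if v.variant_id in important}
        weights = estimate_weights(cohort, risk_dos, important, risk_alleles,
                                   config.covariates)
        profiles = compute_grs(risk_dos, weights)
        cats_u, cut_u = categorize(profiles["unweighted"])
        cats_w, cut_w = categorize(profiles["weighted"])
        profiles["category_unweighted"] = cats_u
        profiles["category_weighted"] = cats_w
        table = pd.concat([cohort[["sample_id"]], profiles], axis=1)
        lio.write_table(table, os.path.join(config.output_dir, "grs.tsv"))
        assoc_u = grs_association(cohort, profiles["unweighted"], cats_u,
                                  config.covariates)
        assoc_u.insert(0, "grs_type", "unweighted")
        assoc_w = grs_association(cohort, profiles["weighted"], cats_w,
                                  config.covariates, per_unit=0.1)
        assoc_w.insert(0, "grs_type", "weighted")
        grs_tab = pd.concat([assoc_u, assoc_w], ignore_index=True)
        lio.write_table(grs_tab, os.path.join(config.output_dir,
                                              "grs_association.tsv"))
        strat = []
        for strat_col in ("sex", "age_group"):
            s = stratified_grs(cohort, profiles["unweighted"], cats_u,
                               strat_col, config.covariates)
            s.insert(0, "stratifier", strat_col)
            strat.append(s)
        strat_tab = pd.concat(strat, ignore_index=True)
        lio.write_table(strat_tab, os.path.join(config.output_dir,
                                                "grs_stratified.tsv"))
        bundle["grs"] = {"weights": weights, "profiles": profiles,
                         "cutpoints": {"unweighted": cut_u, "weighted": cut_w},
                         "association": grs_tab, "stratified": strat_tab}
        runlog["stages"]["grs"] = {
            "weights": weights.betas, "cutpoints_unweighted": cut_u,
            "cutpoints_weighted": cut_w,
            "n_incomplete": int((~profiles["complete"]).sum())}

    if "interaction" in config.stages:
        if profiles is None:
            raise RuntimeError("interaction stage requires the GRS stage")
        rng = np.random.default_rng(seeds["interaction"])
        results = []
        for score_type in ("unweighted", "weighted"):
            high = (profiles[f"category_{score_type}"] == "high").astype(float)
            high[profiles[score_type].isna()] = np.nan
            for exposure in ("sleep", "physical_activity"):
                res = bootstrap_interaction(
                    cohort, high, cohort[exposure],
                    B=config.n_bootstrap, seed=int(rng.integers(2**31)),
                    covariates=config.covariates,
                    grs_label=f"{score_type} GRS", exposure_label=exposure)
                results.append(res)
        inter_tab = interaction_report(results)
        lio.write_table(inter_tab, os.path.join(config.output_dir,
                                                "interaction.tsv"))
        bundle["interaction"] = results
        runlog["stages"]["interaction"] = {
            "n_blocks": len(results),
            "dropped_resamples": {f"{r.grs_label}/{r.exposure_label}":
                                  r.n_dropped for r in results}}

    with open(os.path.join(config.output_dir, "run_log.json"), "w") as fh:
        json.dump(runlog, fh, indent=1, default=str)
    bundle["runlog"] = runlog
    return bundle


def important_variants(assoc: Optional[pd.DataFrame], tree: Optional[Tree],
                       cohort: pd.DataFrame, alpha: float = 0.05
                       ) -> list[str]:
    """Union of permutation-significant single-locus variants (dominant or
    additive model) and variants on the path to the highest-risk CART
    terminal node, in genotype-column order."""
    sig: set[str] = set()
    if assoc is not None:
        hits = assoc[(assoc["model"].isin(["dominant", "additive"]))
                     & (assoc["p_permutation"] < alpha)]
        sig.update(hits["variant"])
    if tree is not None:
        terminals = tree.terminal_ids()
        best = max(terminals, key=lambda i: (tree.nodes[i].case_proportion, -i))
        sig.update(_path_variants(tree, best))
    order = genotype_columns(cohort)
    return [v for v in order if v in sig]


def _path_variants(tree: Tree, terminal_id: int) -> set[str]:
    parents = {c: (nid, nd.split.variant_id)
               for nid, nd in tree.nodes.items() if nd.children
               for c in nd.children}
    out = set()
    nid = terminal_id
    while nid in parents:
        nid, vid = parents[nid]
        out.add(vid)
    return out


def make_fixture(out_dir: str, seed: int = 1, n_cases: int = 1123,
                 n_controls: int = 1231, n_pool: Optional[int] = None,
                 missing_rates: Optional[dict[str, float]] = None
                 ) -> dict[str, str]:
    """Write a study-like synthetic VCF + phenotype TSV + pipeline config.

    Default sizes emulate the motivating cohort (~1123/1231, 12 variants);
    a light default missingness touches one GRS variant and the lifestyle
    columns so the footnoted-denominator logic is exercised.
    """
    os.makedirs(out_dir, exist_ok=True)
    cfg = study_like_config(n_cases=n_cases, n_controls=n_controls, seed=seed)
    if missing_rates is None:
        missing_rates = {"rs12970134": 0.0017,
                         "physical_activity": 0.02, "sleep": 0.02}
    cohort, report = simulate_cohort(cfg, n_pool=n_pool,
                                     missing_rates=missing_rates)
    variants = [v.to_variant_info() for v in cfg.variants]
    dosages = cohort.set_index("sample_id")[[v.variant_id for v in variants]]
    vcf_path = os.path.join(out_dir, "genotypes.vcf")
    pheno_path = os.path.join(out_dir, "phenotypes.tsv")
    lio.write_vcf(dosages, variants, vcf_path)
    lio.write_phenotypes(cohort, pheno_path)
    pconf = {
        "genotypes": vcf_path, "phenotypes": pheno_path,
        "genotype_format": "vcf",
        "risk_alleles": {v.variant_id: v.risk_allele for v in variants},
        "gene_labels": {v.variant_id: v.gene_label for v in variants},
        "seed": seed, "output_dir": os.path.join(out_dir, "results"),
    }
    import yaml
    conf_path = os.path.join(out_dir, "pipeline.yaml")
    with open(conf_path, "w") as fh:
        yaml.safe_dump(pconf, fh, sort_keys=False)
    return {"vcf": vcf_path, "phenotypes": pheno_path, "config": conf_path}


def load_pipeline_config(path: str) -> PipelineConfig:
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    return PipelineConfig(**data)
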