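# Methods

## Study design being emulated

The package analyses a frequency-matched case-control study of childhood
obesity: ~1123 cases and ~1231 controls, 12 biallelic candidate variants
in the leptin–melanocortin pathway genotyped per sample, plus categorical
covariates (sex, age band 7–8 / 11–14 / 15–18, school grade, parental
education, household income) and two binary lifestyle exposures (physical
activity and sleep, adequate vs inadequate). Since the individual-level
data are unavailable, a synthetic-cohort generator provides inputs with
the same statistical structure, and published summary numbers (2×2
counts, adjusted odds ratios) serve as reference inputs for exact
desk-check reproductions.

## Synthetic cohort

**Model.** A population pool of configurable size is drawn first:
genotypes per locus are multinomial with ALT-dosage probabilities
(q² + ε, 2pq(1−f), p² + ε) where p is the configured allele frequency and
f an optional inbreeding-like HWE-departure coefficient (ε = pqf
symmetrically restores the removed heterozygote mass). Covariates and
lifestyle exposures are categorical draws, independent of genotype (the
emulated study found no case-control covariate differences; confounding
is therefore not built in). Disease status is Bernoulli with

    logit P(case) = β₀ + Σᵥ βᵥ·dᵥ + Σₑ βₑ·1[exposed]ₑ + interaction terms,

dᵥ the risk-oriented dosage. All requested cases are then sampled from
the pool and controls are frequency-matched to them on sex, age group and
school (largest-remainder apportionment of the case cell proportions;
per-cell shortfalls reallocated proportionally and reported). Sampling
case-control from a prospective-logistic pool keeps the logistic odds
ratios of the disease model valid in the sampled data, which is the
property the downstream estimators rely on.

**Default ("study-like") parameters.** Four effect variants with
per-allele log-odds 0.268, 0.217, 0.110, 0.044 (the published
additive-model coefficients) and eight null variants. Risk-allele
frequencies for the effect variants are 0.22, 0.20, 0.10, 0.25 — chosen
once so that P(unweighted GRS = 0) ≈ 0.18, matching the published share
of zero-risk-allele carriers (428/2350); per-variant frequency tables
were not published. Null-variant MAFs span 0.10–0.45. Lifestyle
prevalences: 86% inadequate physical activity, 80% inadequate sleep, with
no lifestyle main effect by default. Baseline log-odds −2.45 (≈8%
population risk), sized so a 20× pool yields the requested cases. The
default fixture adds MCAR missingness: 1.7/1000 on one GRS variant
(emulating the four missing genotypes footnoted in the original tables)
and 2% on each lifestyle variable.

**What the generator does not emulate.** No linkage disequilibrium
between variants (the emulated study preselected variants with r² < 0.8),
no genotype–covariate dependence, no genotyping batch effects, no
informative missingness, no continuous BMI outcome. Passing tests
therefore demonstrate correctness of the estimators under the assumed
sampling model, not robustness to confounding or LD.

## Estimators and numerical choices

**Logistic regression.** IRLS from a zero start; convergence when both
max|score| and max|Δβ| fall below 1e-8 (max 100 iterations); Wald
covariance from the inverse observed information at the final iterate;
|β| > 15 flags (quasi-)complete separation — flagged, not corrected (no
Firth). Covariates enter as indicator columns with the first observed
level as reference; age enters as its band. Rows with any missing value
in the used columns are dropped per model, so samples missing a lifestyle
variable stay in all genetic analyses (this reproduces the
footnoted-denominator convention of the emulated study).

**Permutation correction (association).** Per-test (not max-T family-wise),
because the emulated study reports one permutation p per contrast with
magnitudes tracking the asymptotic p. The genotype column is permuted
against the (status, covariates) rows — equivalent to permuting
status+covariates jointly against genotype — which preserves the
status–covariate association exactly under the null of no genetic effect.
Statistic: the term's |Wald z|; p = (1 + #{|z_perm| ≥ |z_obs|})/(B + 1);
non-converged permuted fits drop out of the denominator (warned above 5%).

**HWE.** χ² without continuity correction; the inferential p is the
allele re-pairing permutation p (conditional on allele counts), the
exact-test analogue of the published "1000 permutations" correction whose
precise scheme was unstated. Conditional on allele counts the statistic
is a function of the heterozygote count alone, so the implementation
permutes a canonical minor-allele indicator — making the Monte-Carlo p
exactly invariant to allele relabeling. Being discrete and tie-inclusive,
this p is conservative (super-uniform) rather than exactly uniform under
the null; the asymptotic p is the near-continuous calibration quantity.

**CART.** Candidate splits are nonempty proper subsets of a variant's
observed genotype categories (complement pairs deduplicated); node-size
floors are 100 samples per parent and 50 per child (the published "100
cases" is read as samples — standard CART terminology; a cases-only mode
is a config option). Missing genotypes follow the majority branch (no
surrogate splits; missingness here is <1%). Ties in Gini decrease break
to the lowest variant index, then the lexicographically smallest left
subset, making growth invariant to row order. No cost-complexity pruning:
the emulated study used cross-validation as an accuracy evaluation, not a
pruning criterion, so stopping is purely size- and zero-decrease-based —
on noise-rich inputs this yields deliberately bushy trees whose 10-fold
CV error sits near chance, slightly above 0.5 because splits selected on
noise overfit. Terminal-node ORs come from one adjusted logistic model
with node-membership indicators against the lowest-case-proportion node
(ties to the lowest node id).

**GRS.** Scores use risk-oriented dosages (dosage if ALT is the risk
allele, else 2 − dosage; orientation is applied here, never at I/O, so
scores are invariant to the REF/ALT polarity of input files). Samples
missing any component variant carry no score. Default weights are the
additive-model log-odds re-estimated on the current cohort (the emulated
study's procedure); fixed external weights are accepted for reproduction.
Categories: a distinct score value v is *low* when the pooled empirical
CDF F(v) ≤ 0.25 and *high* when F(v) > 0.75 — quartile cuts snapped to
whole score values, which reproduces the published bins (low = {0},
medium = {1–2}, high = {3–6}) from their category shares; quartiles are
computed on the pooled sample (controls-only available via flag). The
trend p treats the category as ordinal 0/1/2. Stratified analyses drop
the stratifier from the adjustment set and compare coefficients with
Z = (b₁−b₂)/√(se₁²+se₂²); >2 strata add pairwise Z against the first
stratum and a Cochran-Q.

**Interaction.** GRS is dichotomized high vs low/medium. One adjusted
model codes the three non-reference G×E cells as indicators; RERI, AP and
IOR are exact closed forms of the three fitted ORs. Bootstrap: whole
samples resampled with replacement within the case and the control group
separately (preserving the design; unstratified mode via flag), the
adjusted model refit per resample, percentile 2.5/97.5 CIs (BCa not
implemented); resamples with empty cells, non-convergence or separation
are dropped and counted (warned above 10%). Significance is CI exclusion
of 0 (RERI, AP) or 1 (IOR). Note AP = 1 − (OR₁₀+OR₀₁−1)/OR₁₁ is
increasing in OR₁₁ only when OR₁₀+OR₀₁ > 1; the property tests respect
this boundary.

**Pipeline.** Stages run QC → association → CART → GRS → interaction; one
global seed fans out to per-stage seeds via `numpy.random.SeedSequence`,
so reruns are byte-identical and stages can be rerun independently.
"Important variants" for the GRS = union of permutation-significant
single-locus variants (dominant or additive model, p < 0.05;
configurable) and the variants on the path to the highest-risk CART
terminal node.

## Test problem sizes

The calibration checks in the test suite run at sizes chosen to estimate
each property with useful precision while keeping the default suite
quick: 50 random designs for the IRLS-vs-reference oracle; 500 replicates
for null-calibration KS checks (association permutation p at n = 400 with
B = 999; HWE at n = 600, MAF 0.3); 100 study-like cohorts at n =
2000/2000 for per-allele CI coverage (asserted within [90%, 99%]); 100
additive-null cohorts at n = 2000/2000 with B = 200 bootstrap resamples
for RERI CI coverage (asserted within [88%, 100%], ±3 binomial SE around
the nominal 95%). The analysis drivers run the full published-scale
configuration (1123/1231, B = 1000).

## Known limitations

- No exact (enumerative) HWE test, no X-chromosome handling.
- No Firth or exact logistic regression; separation is flagged only.
- No LD-aware scoring or PGS-format interchange.
- The published covariate-adjusted ORs, CART topology and stratified
  estimates depend on the unavailable individual-level data and are
  reproduced only in distribution on synthetic cohorts; exact
  reproduction covers the quantities computable from published
  summary-level inputs (crude ORs, descriptive χ², RERI/AP/IOR closed
  forms).
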