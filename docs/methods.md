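# Methods

This note documents the statistical procedures implemented in
`rvcollapse`, their assumptions, the tunable parameters, and the design
choices made where a convention had to be picked.

## Study design assumed

A case-control study assembled from several cohorts, each sequenced and
QC'd with a shared pipeline, analysed within cohort × ancestry strata and
meta-analysed across them.  Cases may additionally be split into
aggressive and non-aggressive disease, giving three contrasts: all cases
vs controls (risk), aggressive vs non-aggressive cases (severity, a
case-only analysis), and aggressive cases vs controls.  A case is
classified aggressive if ANY of the following holds: tumour stage T4,
nodal stage N1, metastasis M1, Gleason score ≥ 8, disease-specific death,
metastatic disease, chemotherapy treatment, or castration resistance;
missing fields count as criterion-not-met, and a case with every field
missing is classified non-aggressive with a `severity-unknown` audit flag
(the non-aggressive stratum absorbs unclassifiable cases, but the flag
preserves auditability).

## Variant and genotype quality control

Two stacks, applied to pipeline PASS calls.

**Collapsing stack** (per genotype): depth DP ≥ 10 (interpreted
per-genotype, since the rule sits among genotype-level criteria); CCDS
transcript membership (a boolean annotation column — no transcript-set
lookup at run time); heterozygous alt-read fraction in [0.3, 0.8];
two-sided exact binomial test of the alt fraction against 0.5 retained
when p > 1×10⁻⁶; GQ ≥ 30; and site-level QUAL ≥ 30, FS ≤ 60 (SNVs) / ≤ 200
(indels), MQ ≥ 40, MQRS ≥ −8, RPRS ≥ −2; gnomAD 10×-coverage fraction
≥ 0.25; and, for variants observed in gnomAD, exome z ≥ −2.0 and exome
MQ ≥ 30.  A missing metric fails its rule (conservative) and is also
recorded as unevaluable.  Every violated rule is recorded in a filter
audit; pass/fail is the conjunction of all rules and therefore independent
of evaluation order.

**ExWAS stack** adds: homozygous-alt calls require alt fraction ≥ 0.8; the
site is excluded when ≥ 1% of samples have DP < 10, when > 0.5% of
genotypes fail any genotype rule, when ≤ 50% of gnomAD exomes reached 10×
at the site, or when the Hardy-Weinberg exact test gives p < 1×10⁻¹⁰.
Imputed-array cohorts additionally filter on imputation INFO ≥ 0.6.

Both exact tests use the minimum-likelihood two-sided convention (sum of
point masses not exceeding the observed mass, with a 1+1e-7 relative
tolerance, as in the standard R implementations) and are evaluated in log
space so extreme observations keep finite, accurate p-values.  The HWE
test conditions on the observed allele counts (no mid-p correction).

## Qualifying-variant models and collapsing

A QV model is a declarative filter: allowed consequence classes
(protein-truncating = stop-gain, frameshift, essential splice; missense;
synonymous), a gnomAD MAF ceiling (popmax preferred when available —
controlled by a per-model `use_popmax` registry field), a within-stratum
MAF ceiling computed on QC-passed genotypes (reported per variant as the
maximum over strata, so the ceiling binds in every analysed stratum), and
an optional damaging-predictor requirement (scores arrive as a boolean
annotation; no in-silico prediction is computed).  The shipped registry
(`rvcollapse/data/qv_models.yaml`) defines ten dominant models spanning
ultra-rare to 5%-MAF, PTV-only to any-nonsynonymous, plus a synonymous
negative-control model, and one recessive model; every threshold is
user-overridable, since reasonable deployments differ in these choices.

Dominant carrier: ≥ 1 QV with dosage ≥ 1.  Recessive carrier: a homozygous
QV or ≥ 2 distinct heterozygous QVs, counted without phase (putative
compound heterozygotes; phase is rarely available in cohort VCFs).
Missing genotypes never confer carrier status.  Genes on a user-supplied
exclusion list (e.g. genes known to track batch effects) are dropped from
the carrier matrix before testing.

For external-control designs, controls can be selected from a pool by
exome-wide QV burden: deterministic greedy nearest-count matching without
replacement, cases processed in sample-id order, ties broken by sample-id
order.  Greedy rather than optimal assignment keeps the selection
reproducible and O(n log n); the result reports the mean per-pair count
difference and the standardized mean difference as matching diagnostics.

## Association testing

Within each stratum the carrier 2×2 table is tested with the two-sided
Fisher exact test (log-space hypergeometric enumeration, minimum-likelihood
convention — the convention required to reproduce published contingency
p-values exactly).  Across strata:

* **CMH test**, 1 df, no continuity correction by default (the dominant
  convention in collapsing frameworks; it keeps the single-stratum case
  exactly equal to the Mantel-Haenszel chi-square, and a `continuity`
  argument provides the 0.5 correction).  Strata with degenerate margins
  contribute nothing and are dropped with a warning; an all-degenerate set
  returns p = 1 flagged.  Because published counts are often < 5 per cell,
  an exact alternative is provided: `method="permutation"` compares the
  observed statistic with stratified label permutations, drawn as
  conditional hypergeometrics per stratum.
* **Mantel-Haenszel pooled OR** with the Robins-Breslow-Greenland variance
  for the 95% CI.  A zero denominator yields an infinite OR with an
  undefined CI, flagged rather than silently dropped.

Significance tiers: suggestive = 0.05/n_genes rounded to two significant
figures (exome-wide Bonferroni; 2.6×10⁻⁶ at the default 18,948 genes) and
study-wide = 1×10⁻⁸.  Both are strict inequalities: p equal to a threshold
is not significant.

**Firth logistic regression** (sensitivity analysis): Newton iterations on
the Jeffreys-prior modified score with step-halving, converged when the
gradient norm drops below 1e-8 (at most 100 iterations; non-convergence is
flagged, never silent).  Per-coefficient p-values come from the penalized
likelihood-ratio test — the reduced fit constrains the coefficient to zero
while keeping the full design's information determinant in the penalty
(profile penalized likelihood).  The penalty guarantees finite estimates
under complete separation, the regime rare-carrier analyses live in; the
LRT is preferred to Wald for its better small-count calibration.

## ExWAS and meta-analysis

Dosages build three 2×2 tables per variant — dominant (carriers vs
non-carriers), allelic (alt vs ref allele counts; totals are 2× sample
counts on autosomes) and recessive (hom-alt vs rest); hemizygous-style
input empties the recessive table with a flag.  Each is tested with the
two-sided Fisher exact test.  Cohorts combine by the METAL-style
sample-size-weighted Stouffer method: zᵢ = sign(direction)·Φ⁻¹(1 − pᵢ/2),
weights √Neffᵢ with Neff = 4/(1/n_cases + 1/n_controls) (the case-control
effective size; total-N weighting would over-weight unbalanced cohorts).
Direction for Fisher-based cohorts is the sign of the sample log OR, with
a 0.5 cell correction used only to determine direction in zero-cell
tables.  Input p-values below 1e-300 are clipped there (the smallest value
with a finite normal quantile) and flagged.  Dominant and recessive models
meta-analyse with CMH instead, since Stouffer weights are calibrated for
the allelic/additive statistics.

## Genomic inflation (λ)

The empirical null is built by re-running the same test battery under
permutations of case-control status (stratified within stratum).  The
expected p distribution is the rank-wise mean of each permutation's sorted
−log₁₀ p values; observed and expected p are transformed to χ²₁ quantiles
and λ is the slope of the origin-anchored least-squares regression of
observed on expected quantiles.  λ = 1 exactly when the distributions
coincide; the quantile scale with origin anchoring reduces to the familiar
median-based λ under median regression and is stable for sparse test
batteries.  The number of permutations defaults to 10 — the expected
distribution is an average over permutations, so few are needed for a
stable null at thousands of tests.

## Somatic-artifact screen

Blood-derived clonal somatic mutations (clonal haematopoiesis drivers such
as *TET2*) can masquerade as germline qualifying variants and produce
spurious gene-level associations.  Two orthogonal signatures identify
them: carrier status increases with age, and heterozygous alt-read
fractions sit below the 50% expected of a germline heterozygote.  The
screen tests the first with a two-sided rank-based location test
(Mann-Whitney; exact for tiny groups; robust and assumption-light — a
Firth logistic-on-age alternative is available behind a flag) and the
second with a pooled one-sided binomial test of total alt reads vs total
depth against 0.5.  A gene is flagged only when both are significant;
alphas default to 10⁻³ each and are explicit configuration, since the
published precedent is a qualitative call.  Degenerate carrier groups
(< 2 on a side) return p = 1 flagged rather than erroring.

## Synthetic cohorts

The generator emulates the multi-cohort stratified design: cohorts with
configured case/control sizes and aggressive fractions (clinical fields
are drawn consistently with the intended class and then run through the
severity classifier, so the classifier is on the data path); per-gene
carrier frequencies and odds ratios with **exact odds scaling** — carrier
odds in cases are control odds × OR (aggressive cases additionally × the
severity OR) — so the configured OR is identifiable as the large-sample
MH OR; one heterozygous qualifying genotype per carrier; synonymous
variants carry status-independent signal (negative control); two common
non-qualifying background variants per gene in Hardy-Weinberg proportions;
decoy variants designed to violate specific named QC rules
(`qc_fail_fraction` of the catalogue); and an optional somatic gene whose
carrier probability is logistic in age
(p = expit(logit(base) + slope·(age − midpoint))) with heterozygous alt
reads Binomial(DP, mean fraction < 0.5).

Genotype metrics are drawn from configurable defaults — DP negative
binomial around 50× truncated at 12 (exome-like depth, and designed-pass
variants must actually pass the coverage rules), GQ uniform 60–99, germline
het alt reads Binomial(DP, 0.5) truncated into the retained allele-balance
band so planted carriers survive QC.  Only thresholds, not distributions,
are dictated by the emulated pipelines, so these are package choices.

**What the simulator does not model:** linkage disequilibrium and
haplotype structure, imputation error, read-level data, relatedness,
population stratification within a stratum, and variant-calling error
beyond the planted QC failures.  Tests passing on these data therefore
validate the statistical machinery and bookkeeping — carrier logic, QC
rule enforcement, meta-analysis, calibration, artifact recovery — not
robustness to those real-data complications.

## Numerical choices and problem sizes

* All exact-test p-values are computed in log space; sums use logsumexp.
* Fisher/HWE implementations are verified against exact-rational
  enumeration oracles (margins to 60, totals to 200) to 1e-10 relative.
* Calibration checks (type-I error, λ, CI coverage, artifact flag rates)
  run on directly sampled carrier tables/matrices at two strata of
  10k vs 10k (coverage), 2k + 1k strata × 2000 replicates (type-I),
  4000 samples × 2000 genes (λ), and 4000-sample cohorts × 100/1000
  replicates (artifact power/specificity) — sizes chosen so binomial noise
  on the checked rates is small relative to the acceptance bands.
* Null-uniformity KS checks run at carrier counts large enough for the
  χ²₁ reference to hold (hundreds of carriers per table); at very sparse
  counts the discrete CMH statistic is expected to deviate, which is why
  the exact permutation mode exists.
* The full VCF → QC → collapse → test path is exercised end-to-end at
  cohort sizes of a few hundred samples, where planted carrier counts are
  recovered exactly from the ground truth.

## Known limitations

* The recessive model ignores phase; two cis hets count as a carrier.
* The within-stratum MAF ceiling is conservative in very small cohorts,
  where a handful of carriers can exceed a 0.1% ceiling; the 5%-ceiling
  models are the appropriate ones at fixture scale.
* Covariate-adjusted CMH and conditional/joint gene models are out of
  scope; Firth regression is the adjusted route.
* The Fisher implementation enumerates the hypergeometric support and is
  meant for the rare-variant regime (support size ~ carrier count), not
  for common-variant allelic tables with tens of thousands of carriers.
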