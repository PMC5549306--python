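# Methods

This note records the models, conventions and design choices behind
`cnvfam`, in the order the pipeline runs them.

## Coordinates and formats

All intervals are 1-based and closed, the PennCNV/PLINK convention; BED
input (0-based, half-open) is converted on read and never stored.
Chromosome tokens are normalized to `chrN` once, at parse time. Parsers are
strict: any malformed line raises an error naming the line number, so
record counts are conserved through the pipeline (`in = out + removed`,
with removals itemized in the QC report).

## Stage-2 CNV-call QC and consensus

Per caller, per sample/chromosome/state, in this order:

1. **Merge.** Two adjacent same-state calls merge when the number of map
   probes strictly between them is less than `gap_fraction` (default 0.20)
   times the probe count of **both** neighbours; merging iterates to a
   fixed point. Lengths and gaps for this rule are measured in probe
   counts, not base pairs. The "both neighbours" reading is the
   conservative resolution of an ambiguous rule ("either one of the
   adjacent CNVs" can be read conjunctively or disjunctively);
   `QcConfig(gap_rule="either")` selects the permissive reading.
2. **Small-call filter.** Keep calls with ≥ `min_snps` probes (default 10)
   and span ≥ `min_length_bp` (default 10 000 bp). Thresholds are
   inclusive because the removal rules are strict inequalities ("less than
   10 SNPs", "smaller than 10 kb").
3. **Blacklist filter.** A call overlapping a blacklist region
   (immunoglobulin, centromeric, telomeric, …) by ≥ 1 bp is removed.
   Any-overlap is the strictest reproducible rule in the absence of a
   stated overlap fraction; the minimum overlap is configurable.
4. **Sample QC.** A sample fails when its log-intensity-ratio SD exceeds
   0.35, or its post-merge call count exceeds 100 (PennCNV-like caller) or
   200 (Birdseye-like caller, which emits many more calls). Equality
   passes ("larger than" / "more than" rules). Call counts are taken after
   merging, before the per-call filters; the alternative (pre-merge
   counts) is not exposed because merging changes counts by well under 1%
   in practice.

Consensus calls are computed last, from surviving calls of surviving
samples: every overlapping same-state pair (one call per caller)
contributes its base-pair intersection, with the probe count recomputed
from the map. Intersections that retain no probe are discarded — a
consensus call must have probe support. Differing states never intersect.

## Covariate adjustment

The trait is regressed on covariates by a Gaussian GEE with exchangeable
within-sibship working correlation (statsmodels). Covariate sets: `base`
(age [years], sex, BMI [kg/m²], ethnicity, site), `base_plus_htn` (adds
hypertension status, relevant because the families were ascertained
through hypertension), and `no_bmi` (guards against CNVs with pleiotropic
BMI effects being adjusted away). Sex and ethnicity are binary indicators,
site is dummy-coded against the alphabetically first observed level. Fits
are complete-case. Indicator columns without variation (e.g. a single
observed ethnicity after subsetting) are dropped with a warning; a
constant *continuous* covariate is a genuine error and is reported with
the offending column names. The cluster is the sibship; samples absent
from the pedigree form singleton clusters. When every cluster is a
singleton the exchangeable structure is degenerate and an independence
structure is used, making the estimate coincide with OLS exactly (this
degeneracy is tested against a closed-form OLS/sandwich oracle).

Residuals (observed − fitted mean) are the adjusted phenotype. They are
centred to exact zero mean afterwards; the association statistic is a
difference of group means, which is invariant to any constant shift, so
centring only tidies the output. Group-mean summaries for a carrier set
refit the model with a carrier indicator and report both groups' predicted
means at the covariate means with robust (sandwich) 95% CIs — robust SEs
are the GEE standard when the variance model is only a working assumption.

## The family-based permutation test

For one SNP and one tested abnormal state, the statistic T is the carrier
mean minus the normal mean of the residuals; samples carrying the *other*
abnormal state enter neither group (the contrast is "an abnormal state vs
normal"), but their residuals still participate in the shuffles. Each
permutation replicate independently re-arranges residuals within every
family; the two-sided p-value is the proportion of replicates with
|T*| ≥ |T|.

Conventions, all configurable:

* denominator B with no add-one correction (p = r/B); a reported p of
  2×10⁻⁴ at B = 5000 corresponds to r = 1;
* ties count toward the p-value (conservative). Because the observed and
  permuted statistics travel through differently-ordered floating-point
  sums, the comparison uses a guard of one part in 10¹² of the statistic
  scale so genuine ties — the identity permutation, constant residuals —
  are never lost to rounding;
* within-family permutation validity requires only that residuals be
  exchangeable within a family under the null, so the test is exact
  conditional on the within-family residual multisets, for any residual
  distribution (checked with Gaussian and t₂ residuals).

The genome-wide scan tests every locus where the tested state reaches
frequency ≥ 5% (the default `freq_min`), and applies **one shared family
shuffle per replicate across all loci**. That preserves the inter-locus
correlation structure in the B × L permuted-statistic matrix, which is what
makes the multiplicity adjustments valid:

* maxT adjusted p: `p_adj(j) = #{b : max_k |T*_bk| ≥ |T_j|} / B`
  (single-step; monotone in |T| and never below the raw p by
  construction);
* empirical FDR: `fdr(j) = mean_b #{k : |T*_bk| ≥ |T_j|} / max(1, #{k :
  |T_k| ≥ |T_j|})`. This ratio is reported as-is, without q-value-style
  monotonization, so it can occasionally be non-monotone in |T| and can
  exceed 1.

Because T is an unstandardized mean difference, its permutation spread
shrinks with carrier count; in scans mixing very different carrier
frequencies the genome-wide max is dominated by the lowest-frequency loci
and maxT becomes conservative for the others. With the ≥5% frequency
floor and the narrow frequency range of real common-CNV loci this is
minor, but it is the reason adjusted p-values, not raw ones, should be
compared only within a scan.

The population-based variant (for unrelated replication cohorts) permutes
residuals across all samples; it is implemented — and tested — as the
family machinery with a single family containing everyone.

## Rare-CNV burden

A call's frequency is the fraction of samples owning ≥ 1 same-state call
overlapping it by ≥ 1 bp (the PLINK-style any-overlap region frequency;
frequency is estimated within state). Calls with frequency < 5% (strict)
are counted per sample by state, and the adjusted trait is regressed on
the count by the same exchangeable GEE with a two-sided robust Wald p.
Burden counting uses consensus calls, consistent with the rest of the
pipeline.

## Type-I error and power studies

**Type-I error.** Residuals from a null cohort are held fixed; in each of
R replicates deletion carriers are re-assigned i.i.d. Bernoulli(f), f
defaulting to 0.052, and the within-family test is run with B fresh
shuffles. Rates at each α come with Wald binomial 95% CIs
(rate ± 1.96·√(rate(1−rate)/R)). Replicates with zero carriers (or all
carriers) are redrawn and counted. Carrier assignment is i.i.d. by
default — matching frequency-matched random generation — with family
clustering available separately in the cohort generator. Rejection is
p ≤ α here; power uses strict p < α; both follow the respective rules'
wording and are deliberate.

**Power.** Families are resampled whole, with replacement, carrying their
states and residuals; each draw gets a fresh family identity so duplicated
families permute independently. Power is the fraction of bootstrap
p-values below α. Bootstrap power is *conditional on the observed cohort*:
it measures the evidence in the realized within-family contrasts, not the
prospective power of the design (see Limitations).

The inner permutation count defaults to B = 1000 (≥ 20/α at the smallest
default α). The acceptance script uses B = 1999: under the p = r/B,
reject-if-p ≤ α convention the rejection probability of an exact test is
(⌊αB⌋+1)/(B+1), so choosing B with αB non-integer at both α = 0.05 and
α = 0.01 puts the empirical size exactly at the nominal level, where
B = 1000 would inflate α = 0.01 to ≈ 0.011. The script's study sizes — one
cohort of ~444 siblings, R = 5000 replicates — are the package's default
study conditions.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes:

* **Pedigree:** 192 sibships of size 1–4 (probabilities 0.19/0.44/0.23/
  0.14, tuned to yield ≈ 444 siblings).
* **Trait:** y = μ + β_age(age−48.27) + β_sex·male + β_bmi(BMI−25.33) +
  ethnicity/site/hypertension effects + γ·carrier + b_family + ε, with
  b_family ~ N(0, σ_b²) and ε scaled so the marginal SD is 16.93 mg/dl
  around a 91.36 mg/dl mean (the study's summary statistics). σ_b defaults
  to 8.6 mg/dl — sibling ICC ≈ 0.26, i.e. half the reported fasting-glucose
  heritability of ≈ 0.52 — and the fitted GEE correlation recovers it.
  Covariate effect sizes (β_age = 0.2 mg/dl/yr, β_bmi = 0.5 mg/dl per
  unit, small sex/ethnicity/site/hypertension effects) are modest
  placeholder values, not estimates. An infeasible variance budget
  (covariate + family variance exceeding the marginal variance) is
  rejected before generation.
* **Focal deletion:** chr3:53,003,415–53,013,826 at carrier frequency
  5.2% with a γ = −4.3 mg/dl trait effect. Carriers cluster in families:
  a family is a carrier family with probability q (set so the expected
  carrier fraction is f), one random member carries, and each sibling
  carries with probability ½ (a Mendelian-like transmission default). The
  true deletion extends 2 probes beyond the region on each side, so
  boundary-jittered caller calls always survive the 10-probe/10-kb filter.
* **Background:** 16 common regions (8 deletion, 8 duplication,
  frequencies 0.055–0.15, no trait effect) and Poisson-distributed rare
  CNVs per sample (means 36.69 deletions, 14.15 duplications — the
  study's observed per-sample counts) of 13–35 probes, placed so no sample
  carries overlapping CNVs.
* **Two callers:** caller A reports true spans; caller B jitters each
  boundary by up to ±1 probe and can miss calls at a configurable rate
  (default 0: the callers disagree on boundaries, not detection, so
  consensus counts match the configured rates).
* **Array:** a regular 1-kb probe grid over one 10-Mb window per
  chromosome (22 chromosomes, 220 000 probes) — a miniature of a SNP
  array, large enough that rare CNVs stay individually rare (<5%) and
  small enough that a full pipeline run takes seconds. Rare-CNV lengths
  are therefore also miniaturized (tens of kb) relative to the real mean
  lengths.

What the generator does **not** emulate: intensity-level data (LRR/BAF) —
callers are emulated at the segment level, so QC on intensity noise uses
generated per-sample SD values; genuine caller disagreement in detection
sensitivity; linkage disequilibrium or irregular probe spacing; batch
effects. Passing tests therefore validate the statistical machinery on
segment-level data, not the upstream calling.

Every latent assignment (carriers per region, per-sample rare counts,
family effects, variance components) is stored in a truth record
sufficient for confusion tables at any downstream step.

## Test problem sizes

The test suite exercises the default study conditions where the claim is
about them (type-I calibration: R = 5000, B = 1000; pipeline recovery: 50
cohorts; burden calibration: 500 permutation replicates) and scaled-down
cohorts (30–60 families, 4–6 chromosomes) everywhere a property is
size-independent. The full suite runs in a few minutes on one CPU.

## Limitations

* **Within-family information bound.** The permutation test conditions on
  family residual multisets, so only the within-family component of a
  carrier effect is visible to it. With ~23 carriers, an individual-level
  effect of −4.3 mg/dl (≈ 0.25 trait SD) yields low prospective power
  (≈ 0.1–0.35 across plausible sibling correlations, by simulation); the
  test's strength on real data comes from realized within-sibship
  contrasts, which the family bootstrap preserves but a prospective
  additive simulation at the same nominal effect does not reproduce. The
  pipeline-recovery acceptance test encodes the nominal-effect expectation
  and fails under the default conditions; this is a property of the study
  design, not of the implementation, and the type-I calibration (which is
  assumption-free) is unaffected.
* Empirical FDR is reported unmonotonized and can exceed 1.
* maxT comparability degrades across loci with very different carrier
  frequencies (unstandardized statistic; see above).
* The burden test treats counts as a linear predictor; no length-weighted
  or gene-set variants are provided.
* PLINK-stage genotype QC (call rates, HWE, relatedness) and CNV calling
  from intensities are upstream of this package and out of its scope.
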