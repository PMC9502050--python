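# Methods

`epomr` re-implements, as a tested library, the statistical chain used in
drug-target Mendelian randomization (MR) studies that anchor a cis-acting
protein-biomarker variant to a clinical-trial effect: per-cohort GWAS of a
rank-normalised biomarker, inverse-variance-weighted (IVW) fixed-effects
meta-analysis, summary-statistics conditional/joint signal selection,
approximate-Bayes-factor (ABF) colocalization against a regional eQTL
signal, single-instrument Wald-ratio MR, and rescaling of per-SD genetic
estimates to a trial-induced exposure change. A synthetic-data generator
supplies cohort-scale inputs with the statistical structure the chain
assumes, so every stage is testable without restricted data.

## Synthetic data

**Genotypes.** Each variant's population allele frequency is drawn uniformly
from `maf_range` (default 0.05–0.5). Two latent Gaussian haplotypes per
sample follow an AR(1) process over variant index with parameter
`rho = 0.5^(1/ld_decay)`; thresholding each latent at `Φ⁻¹(f)` yields
alleles, and their sum the dosage. This gives Hardy–Weinberg proportions at
every variant and LD that decays geometrically with index distance
(`ld_decay` is the index distance at which latent correlation halves;
dosage correlation is slightly attenuated relative to the latent scale, as
usual for threshold models). Columns that come out monomorphic at small n
are redrawn independently — a rare event at the default MAF range and
cohort sizes — so the post-simulation panel is always polymorphic.
The generator does **not** model haplotype-reference realism, imputation
uncertainty, population structure, or relatedness; all samples are
unrelated by construction. Consequently the mixed-model machinery used for
real cohort data is unnecessary here and association uses OLS / logistic
regression. Passing tests therefore demonstrate correctness of the
statistical chain, not robustness to stratification or cryptic relatedness.

**Biomarker.** `phenotype = beta_causal × dosage(causal variant) + e`, with
`e` a shifted log-normal standardised to mean 0, variance 1 (`skew` is the
log-scale sigma; positive support before shifting matches a serum
concentration, and the family has closed-form skewness
`(e^{σ²}+2)√(e^{σ²}−1)` used by the moment tests). Defaults are the study
design this package emulates: four cohorts of 1,210 / 2,954 / 458 / 1,505
(pooled n = 6,127) and `beta_causal = 0.063` SD per allele.

The default `skew = 0.4` (skewness ≈ 1.3) is a deliberate compromise. The
GWAS stage rank-normalises the phenotype, and under an additive model with
non-Gaussian noise the rank-normal-scale slope equals the generative slope
times `E[g'(e)]` with `g = Φ⁻¹∘F_e`. At σ = 1 that factor is ≈ 3, which
would make "the pipeline recovers the planted per-allele effect" false by
construction; at σ = 0.4 the factor is ≈ 1.1, second-order relative to the
sampling SE (≈ 0.021) at pooled n = 6,127, while the phenotype remains
clearly right-skewed — which is what motivates the inverse-normal transform
in the first place.

**Outcome summary statistics** are generated at summary level under a
mediation model (variant → exposure → outcome): the expected per-allele
log-odds is `ln(OR_per_SD) × beta_exposure(variant)`, the SE follows the
binary-trait approximation `1/√(2f(1−f)·n_eff)` with
`n_eff = 4/(1/cases + 1/controls)`, and independent Gaussian noise is
added. Individual-level case-control sampling is unnecessary because the MR
stage consumes only summary statistics.

**eQTL summary statistics** are simulated at individual level (n = 861 by
default) on the same variant panel, with the causal variant either shared
with the biomarker's (colocalization H4 ground truth) or distinct (H3),
then passed through the same association scan, so their noise has the
correct LD structure.

All generators are pure functions of (config, seed). Internal random
streams are keyed (`default_rng([seed, k])`) so that user-level integer
seeds can never alias an internal stream.

## Per-cohort GWAS

The inverse-normal transform maps rank r (average ranks on ties) to
`Φ⁻¹((r − c)/(n − 2c + 1))` with the Blom constant c = 3/8. Association is
additive OLS of the transformed phenotype on dosage; covariates are handled
by Frisch–Waugh–Lovell residualisation of both phenotype and dosages, with
degrees of freedom adjusted. P-values use the normal approximation to the t
statistic (the convention of downstream summary-statistics tools); values
below 1e-320 are floored and flagged rather than stored as zero.

Variant QC follows the two-stage convention: before meta-analysis, minor
allele count strictly greater than `mac_min` (default 3), effect-allele
frequency strictly inside (0, 1), and imputation Info ≥ 0.3; after
meta-analysis, symmetric MAF ≥ 0.01. Every exclusion is logged with a
reason, and the filter is idempotent.

## Meta-analysis

Records are matched across studies on chromosome, position and the
unordered allele pair; swapped-allele records have the effect negated and
the frequency complemented; palindromic (A/T, C/G) variants with
minor-allele frequency above 0.42 are strand-unresolvable from summary
data and dropped by default (configurable). IVW fixed effects:
`w = 1/SE²`, pooled effect `Σwβ/Σw`, SE `1/√Σw`, plus Cochran's Q and a
per-study direction string; Q is reported, never used for filtering (the
analysis is fixed-effects throughout). A sample-size-weighted z-score
scheme (`z_meta = Σ z_i √n_i / √Σn_i`) is provided for eQTL-style inputs
whose effect scales are not comparable across studies.

## Conditional and joint selection

From marginal statistics plus an LD reference, the X'X block of a variant
set is reconstructed as `D^{1/2} R D^{1/2}` with `D_j = var(dosage_j)·n_j`
(per-variant n from the meta-analysis respected via the diagonal) and
`X'y_j = D_j β_j`; the phenotypic sum of squares is recovered per variant
from `D_j(se_j²(n_j−2) + β_j²)` (phenotype assumed variance-standardised).
When the LD correlations and dosage variances come from the same sample as
the summary statistics, the joint solution equals individual-level multiple
regression coefficients — the module's primary oracle, asserted to relative
error < 1e-6 in the tests.

Forward selection seeds with the smallest marginal p below the threshold
(default 5e-8), then repeatedly adds the most significant conditional
candidate below threshold, refits the selected set jointly, and drops any
variant whose joint p rises above the threshold. Candidates with reference
r² > 0.9 (GCTA's conventional cutoff) against any selected variant are
excluded from candidacy and logged; reference correlations beyond a 10 Mb
window are treated as zero. Ties on significance break to the smaller
position, making selection deterministic and input-order invariant.

Numerical choices: conditional effects come from the joint solve of
{selected ∪ candidate}; the conditional SE uses the candidate's *marginal*
residual variance (`D_j se_j²`) rather than the joint one, which makes
conditional statistics reduce exactly to marginal statistics on an
orthogonal panel and is conservative under LD. Joint-fit SEs use the
proper joint residual variance with `n − p − 1` degrees of freedom, which
reduces exactly to the marginal SE for a singleton set. A selected-set
condition number above 1e12 raises an error naming the worst variant pair.

The genome-wide use case (tens of millions of variants) is out of scope;
the module targets regional panels of up to a few thousand variants.

## Colocalization

Per-variant evidence is the Wakefield ABF: with `V = se²`, `W = prior_sd²`,
`r = W/(V+W)`, `log ABF = ½log(1−r) + z²r/2`. Hypothesis weights over a
region are H0: 1; H1: `p1·S1`; H2: `p2·S2`; H3: `p1·p2·(S1·S2 − S12)`
(ordered distinct pairs, computed stably in log space via `log1p(-exp(·))`);
H4: `p12·S12`, normalised to posterior probabilities PP0–PP4. Defaults
`p1 = p2 = 1e-4`, `p12 = 1e-5`, `prior_sd = 0.15` for both (quantitative)
traits are the cited method's conventional values. All sums are evaluated
with `logsumexp`, so |z| up to 40 is exact and finite. Variant panels are
intersected on chrom:pos with allele alignment (re-using the meta-analysis
aligner); an optional p-value pre-filter on the eQTL side emulates
FDR-screened eQTL inputs but is off by default, since filtering coloc
inputs is nonstandard. The single-causal-variant-per-trait assumption is
inherent to the ABF formulation; no SuSiE-style multi-causal extension is
attempted. A mirrored (“Miami”) regional plot is available for inspection.

Note an intrinsic property visible in the tests and acceptance outputs: at
the emulated study scale (biomarker z ≈ 3 at the causal variant), PP4 under
a true shared causal variant is genuinely variable across realisations
(~0.4–0.99) — region-level colocalization evidence at that signal strength
is marginal. The well-powered H4 validation uses effect 0.3 on both traits.

## MR and trial rescaling

Wald ratio: `β_outcome/β_exposure`, first-order SE `se_out/|β_exp|`
(default; the second-order form adding the exposure-uncertainty term
`√(se_out²/β_exp² + β_out²se_exp²/β_exp⁴)` is available by flag). 95% CIs
are normal; binary outcomes are also reported exponentiated, and the OR
scale is the exact exponential image of the log scale. Under a true null,
the first-order t statistic reduces to `β_out/se_out`, so CI coverage is
exactly nominal for a strong instrument — the calibration test asserts
93–97% over 500 replicates. When genotype–outcome associations exist in
two sources, they are IVW-pooled at the instrument before the ratio.

Trial rescaling: a trial shifting the biomarker by `median_change` against
baseline SD `baseline_sd` (defaults 27.1 and 61 IU/L, i.e. 0.44 SD)
defines `scaling_sd = median_change/baseline_sd`; dividing by the
per-allele exposure effect gives the per-allele factor (7.05 at 0.063 SD).
Log-odds (or linear) points and both CI bounds scale linearly in
`scaling_sd`, so odds ratios are raised to the power `scaling_sd`. The
rescaled harm-direction CI bound (upper, for disease outcomes) is reported
as the exclusion bound — the largest adverse effect compatible with the
genetic data. Unit conversion between SD and natural units multiplies by
`sd_in_natural_units` (default 5.1 IU/L per SD). Rescaled CI bounds are
computed from the (unrounded) per-SD bounds; reproducing published rescaled
bounds from *rounded* per-SD inputs is not generally possible and only the
rescaled point estimates are treated as reproducible arithmetic.

## PheWAS

One variant's dosage is scanned against a trait matrix: continuous traits
are inverse-normal transformed then fit by OLS; binary traits by logistic
regression (statsmodels); per-trait complete-case n is recorded; traits
with fewer than two distinct values or failed fits are emitted with status
`degenerate` so the output always has one row per trait. The significance
flag uses a fixed 5e-8 threshold (configurable); no further
multiple-testing correction is applied. Synthetic traits are unstructured
null (or optionally effect-injected) stand-ins; no trait ontology or
curation is modelled.

## Orchestration and problem sizes

The pipeline (simulate → cohort GWAS → meta → conditional selection →
coloc → MR/rescale → PheWAS) is driven by a YAML config that round-trips
exactly; all randomness derives from the config seed, outputs carry no
timestamps, and a rerun is byte-identical. Each stage writes a provenance
record (inputs, parameters, seed, version). Coordinates are 1-based;
intervals closed.

Default problem sizes are the emulated design where stated (pooled
n = 6,127 over four cohorts; eQTL n = 861; outcome case counts ~98.5k
cases for the combined CAD sources) and package choices elsewhere: a
120-variant regional panel, 869 PheWAS traits at n = 5,000 (a phenome scan
at biobank scale is not reproducible at desk scale; the effect-detection
test instead checks a 0.02 SD effect at n = 400,000 for a single trait).
Validation scenarios pick effect sizes for decisive power: the two-signal
conditional-selection check plants 0.15 SD effects at MAF ≥ 0.25,
n = 10,000, so conditional z ≈ 8–9 against the 5e-8 threshold.

## Known limitations

- No mixed models: relatedness and stratification are absent by
  construction, so the OLS stage is not a general replacement for
  GEMMA/BOLT-LMM on real cohorts.
- Single-instrument MR only; pleiotropy-robust estimators (IVW across
  variants, Egger, weighted median) are out of scope for a single cis
  instrument.
- Summary-level outcome simulation adds independent per-variant noise;
  cross-variant noise correlation matters only for multi-variant outcome
  analyses, which this package does not perform.
- The COJO stage assumes a variance-standardised phenotype; effect sizes on
  other scales must be standardised first.
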