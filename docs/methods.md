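# Methods

This note documents the statistical procedures, the defaults, and the
design choices behind them. Symbols: β_i is the per-allele weight of SNP
*i*, x_ij ∈ [0, 2] the effect-allele dosage of individual *j*, n the SNP
count of a score.

## Score definition and scoring

A score is an ordered set of variants, each with an effect allele (the
LDL-C-raising allele), an other allele, and a weight in mmol/L per allele.
The score value is the raw weighted sum `PRS_j = Σ_i β_i x_ij` — no
per-SNP averaging and no standardisation — because the packaged risk-class
cutoffs are defined on the raw-sum scale. For all-positive weights the
score lies in `[0, 2Σβ]`; for the packaged 36-SNP score `Σβ = 4.3185`, so
valid scores lie in [0, 8.637] (the published cohort score ranges,
4.13–7.60, sit inside this interval).

**Allele alignment.** Score variants are matched to a genotype matrix by
rsID, falling back to (chromosome, position). If the effect allele is the
counted (ALT) allele the dosage enters directly; if it is the REF allele
the contribution is β·(2 − x). Strand-ambiguous palindromic variants (A/T,
C/G) cannot be oriented when the minor-allele frequency is near 0.5; the
default policy drops them when the in-sample MAF is in (0.4, 0.5] and
orients by allele match otherwise (`keep` and `drop` policies are
available). Unmatched variants are dropped with a recorded reason; a score
with no matching variant at all is an error.

**Missingness.** Missing dosages at scored variants are imputed to twice
the in-sample effect-allele frequency (the per-variant mean), the standard
choice for score stability. A variant with no observed genotype cannot be
imputed and raises.

## Clumping and the threshold scan

LD is always the squared Pearson correlation of in-sample dosages, computed
within a physical window after per-variant mean imputation of missing
cells. Clumping is greedy: repeatedly promote the most significant
unprocessed SNP to index status and remove all unprocessed same-chromosome
SNPs within the window whose r² with the index reaches the threshold.
Defaults: window 250 kb each side (the conventional clumping window; the
procedure this mirrors does not fix one), r² threshold 0.1 (the value that
gave the best model fit in the validation study this score derives from).
P-value ties are broken by (chromosome, position, rsID); pairs with
undefined r² (zero dosage variance) never cause removal. The greedy output
partitions the input: every SNP is either an index or assigned to exactly
one index with smaller-or-equal p and r² at or above threshold.

The threshold scan rebuilds the score at each grid point (SNPs with
p < threshold, weights = summary-statistic betas), scores the cohort, and
computes the incremental R². The default grid is log10-spaced with step 1
from 10⁻³ to 10⁻¹⁰⁰ (98 points); the range is the published one, the
spacing a package choice. The best threshold maximises incremental R²;
exact ties resolve toward the more stringent threshold (fewest SNPs), a
parsimony rule that also makes the selection deterministic on the flat
plateaus that arise when consecutive thresholds retain identical SNP sets.
Thresholds retaining zero SNPs are recorded with undefined fit, never
fatal.

**Incremental R².** Ordinary least squares on complete cases; incremental
R² = R²(LDL-C ~ PRS + covariates) − R²(LDL-C ~ covariates), using the
plain (unadjusted) coefficient of determination on both sides (adjusted R²
is available behind a flag but is never the default, since the
full-minus-null definition is stated in plain R²). The reported model
p-value is the Wald p of the PRS coefficient in the full model. Default
covariates: age, sex, BMI and the first two MDS components.

**Ancestry covariates.** The sample distance is allele-sharing identity by
state, d(i,j) = mean(|x_i − x_j|)/2 over variants non-missing in both,
hence in [0, 1]. Classical (Torgerson) MDS double-centres the squared
distances and eigendecomposes; coordinates are scaled by √eigenvalue,
negative eigenvalues (non-Euclidean input) truncate to zero with a
warning, and component signs are fixed by forcing the largest-magnitude
loading positive so runs are reproducible. For more than 2,000 samples
only the top-k eigenpairs are computed (Lanczos) rather than the full
spectrum.

## Risk stratification

Phenotype classes use the clinical LDL-C bands: severe HC strictly above
4.9 mmol/L, intermediate HC in [3.0, 4.9], normal below 3.0.

Score classes follow the decile categorisation of the 12-SNP raising-score
practice: bottom three deciles low, deciles 4–6 intermediate, top four
high, i.e. class fractions (0.3, 0.3, 0.4). The cutoffs are the
floor(f·n)-th order statistics of the cohort's scores, so with all-distinct
scores the low class holds exactly floor(0.3·n) samples and ties share the
lower class; classification is `score ≤ c_low → low`,
`c_low < score ≤ c_high → intermediate`, `score > c_high → high`, and is
invariant to strictly monotone transforms of the score. The published
counts for the construction cohort (659/879/659 of 2,197) instead imply
fractions (0.3, 0.4, 0.3) — the two conventions disagree in the source
material, so the fraction triple is a configuration knob with
(0.3, 0.3, 0.4) as default. Cutoffs are plain score values, serialized
with a provenance tag, and transfer unchanged between cohorts; the
packaged 36-SNP score ships the published pair (5.98, 6.44).

## Comparison statistics

* **Risk ratio** — (events_high/n_high)/(events_low/n_low) with the Katz
  log-normal 95 % CI and a two-sided p from the log-RR z statistic; when
  an event cell is zero, 0.5 is added to all four cells. The source names
  no CI method; Katz is the standard choice.
* **Wilcoxon rank-sum** — exact enumeration of all rank assignments
  (tie-aware) when both groups have ≤ 8 observations, tie-corrected normal
  approximation above that. All-identical inputs return p = 1 with a
  warning.
* **ROC/AUC** — Mann–Whitney concordance probability with half credit for
  ties.
* **DeLong test** — paired-AUC comparison via structural components
  (placement values); the covariance term accounts for both scores being
  computed on the same samples. Identical score vectors short-circuit to
  z = 0, p = 1.
* **Reclassification / concordance** — 3×3 cross-tabulation (rows score A,
  columns score B) with conserved marginals; the low-class summary is the
  fraction moved to a higher class, pooling numerators and denominators
  across cohorts before dividing; concordance counts only both-high and
  both-low agreement. Percentages round half-up to integers, matching the
  reporting convention of the source material.

## The synthetic cohort generator

The generator emulates the *statistical* structure the pipeline assumes,
not real genomes.

* **Genotypes** — per LD block, each of an individual's two haplotypes
  receives a latent multivariate-normal vector with exchangeable
  correlation √r²_target; an allele is carried where the latent value
  falls below the frequency quantile, and haplotypes sum to a dosage in
  {0, 1, 2}. Marginal frequencies are exact in expectation; the realized
  dosage correlation is mildly attenuated relative to the latent one by
  thresholding. Blocks are mutually independent. Default frequencies for
  the 36 packaged loci are drawn once per seed from Uniform(0.05, 0.5) —
  the score publishes no allele frequencies, so this is an arbitrary,
  documented choice.
* **Covariates** — age normal, sex Bernoulli (1 = male), BMI log-normal
  matched to a median/IQR target, smoking Bernoulli. The two built-in
  profiles mirror the validation study's cohorts: construction (age
  60 ± 11.5, 49 % male, BMI 27.8 (24.9–31.4), 31 % smokers, LDL-C median
  3.60, IQR 3.08–4.11 mmol/L; n = 2,197) and replication (age 31 ± 0.2,
  48 % male, BMI 23.9 (21.9–26.6), 37 % smokers, LDL-C median 2.90, IQR
  2.40–3.50; n = 4,787).
* **Phenotype** — LDL-C = intercept + c·PRS + covariate terms + Gaussian
  noise. The total-variance target is ((Q3 − Q1)/1.349)², c is solved from
  the *realized* score variance so that c²·var(PRS) equals the target
  incremental share (default 0.08), and the noise variance absorbs the
  remainder after the covariate contribution (an infeasible combination
  raises). The intercept shifts the empirical median onto the target.
  Covariate effects default to 0.01 mmol/L per year of age, 0.10 for male
  sex, 0.02 per BMI unit and 0.05 for smoking — magnitudes in the range of
  reported epidemiological associations; they matter only through their
  (small) variance contribution. Non-positive values after the shift are
  truncated to 0.1 mmol/L with a logged count (essentially never triggered
  at the default location/scale). Gaussian noise is a deliberate
  simplification: real LDL-C is right-skewed, so passing tests show the
  pipeline recovers its own model's parameters, not that the model fits
  real lipid distributions.
* **Summary statistics** — causal variants report their true beta with
  p = 10^−U(20, 100) (the packaged score's SNPs all had p < 10⁻²⁰ in the
  source GWAS); other variants report N(0, 0.01²) betas with p ~ U(0, 1),
  or a configurable exponent range for planting decoys.
* **Determinism** — one mandatory seed spawns four named child streams
  (genotypes, covariates, noise, summary statistics), so changing, say, a
  covariate coefficient leaves the genotype draw bit-identical.

What the simulator does **not** model: population stratification
confounding (MDS components in simulated data capture noise, not
ancestry), linkage to untyped causal variants, genotyping/imputation
error, haplotype-level structure beyond exchangeable within-block
correlation, and LDL-C skew. Recovery results on synthetic data therefore
validate the estimator chain, not real-data effect sizes.

## Packaged data

* `ldl_prs_36snp.tsv` — the 36-SNP LDL-C score: rsID, GRCh38 position,
  non-effect/effect alleles, GLGC weight, gene label and source p-value,
  plus the published cutoffs (5.98, 6.44). The distinct-gene count
  excludes intergenic markers and non-symbol labels (versioned accessions
  like `AC115619.1`, RNA-family ids like `RF00285`), yielding 23 genes
  from 27 distinct non-intergenic labels; the counting rule is chosen to
  match the published gene count, which states no rule.
* The 12-SNP raising-score comparator is packaged as a structural rsID
  list (five entries shared with the 36-SNP score carry full metadata).
  Its weights are not published in the source material, so scoring it
  without supplying weights (`ScoreDefinition.with_weights` or a scoring
  file) raises deliberately.

## Problem sizes in the shipped studies

The test suite and the acceptance script run the recovery study at
n = 10,000 over 20 seeds per variance share, null calibration at n = 5,000
over 3 cohorts, clumping-oracle comparison on 100 random instances of ≤ 15
variants, and the end-to-end pipeline at 1,200/2,400 samples with 60 null
loci — sizes at which every Monte-Carlo tolerance in the tests is a ≥ 2-SE
bound while a full run stays in the tens of seconds.

## Known limitations

* LD is always in-sample; there is no reference-panel LD, so clumping on a
  small cohort inherits its LD noise.
* Strand-flip detection is allele-letter based; a score and VCF on
  opposite strands at a non-palindromic SNP are reported as allele
  mismatches rather than silently complemented.
* Binary-trait (logistic) scans, Bayesian/penalized weights (LDpred-style),
  NRI statistics and genotype imputation are out of scope.
* The empirical-quantile cutoff rule is one of several defensible
  conventions; cutoff values (not classes) can differ from other tools by
  one order statistic on tied or small cohorts.
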