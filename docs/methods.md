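# Methods notes

## Scope and data model

`metsgxe` implements an age-at-menarche (AAM) × genotype interaction
analysis of metabolic-syndrome (MetS) traits as a five-stage pipeline:
phenotyping → category-wise epidemiologic models → genome-wide G×E scan →
pathway enrichment, with a synthetic-data generator standing in for the
restricted reference cohort (KARE: 3,180 Korean women aged 40–69,
344,396 post-QC SNPs from an Affymetrix 5.0 array). All estimands and
thresholds follow the reference analysis; everything below documents the
choices that analysis left open and the behaviour of the synthetic
experiments.

## Phenotyping

* Exclusions: AAM ≤ 10, AAM ≥ 19, or missing AAM, applied in that order,
  with per-reason counts. AAM = 11 is retained (11 and 12 pool into the
  early category).
* Categories: ≤12 / 13 / 14 / 15 / 16 / ≥17 years, reference 16 (the
  cohort median). "Early menarche" is category ≤12.
* MetS (NCEP-ATP III, Korean waist cutoff): central obesity WC ≥ 85 cm;
  TG ≥ 150 mg/dl; HDL < 50 mg/dl; SBP ≥ 130 **or** DBP ≥ 85 mmHg or
  antihypertensive medication; FG ≥ 100 mg/dl or antidiabetic
  medication; MetS = ≥ 3 components. Boundary ties resolve by the
  printed symbols ("≥" inclusive, "<" strict). The "either-or" reading
  of the 130/85 blood-pressure cutoff is the standard ATP-III one.
  Medication flags force their component regardless of measured values.
* Missing component inputs yield a missing MetS status with a recorded
  reason. Nothing is imputed — the reference analysis describes none.

## Epidemiologic models

One model per outcome: five category dummies (reference omitted) plus
covariates age, area (binary, urban = 1), income and education (ordinal
0/1/2 scores — the coding is not stated in the reference analysis and is
configurable here), and CRP. Logistic fits are maximum likelihood via
IRLS (tol 1e-8, ≤ 100 iterations, statsmodels GLM); linear fits are OLS.
95% CIs use the normal multiplier 1.959964; linear p-values are t-based.
The reference row is printed as 0 (OR 1) with no CI: under this
parameterisation the reference category has no sampling variance of its
own, so the nonzero reference CIs sometimes seen in published tables are
not derivable from the stated model and are not reproduced. Baseline
descriptives use tie-corrected Kruskal–Wallis (continuous) and Pearson
chi-square without continuity correction (categorical). The published
per-category percentages for categories 14/15/≥17 (16.6/21.1/29.8) do
not match count/3180 rounding (16.7/21.0/29.7); this package reports the
recomputed values.

## G×E scan

* QC: drop SNPs with missing-call proportion > 0.5% or MAF ≤ 0.05
  (inclusive at the boundary, as printed).
* Per SNP: Y ~ 1 + E + G + G·E + covariates, complete-case over the
  SNP's missing dosages, with the per-SNP n recorded. The linear fitter
  solves the normal equations directly (fast enough for ~10⁴ fits/s);
  the logistic fitter is a Newton/IRLS implementation (tol 1e-8,
  ≤ 100 iterations). Both are cross-checked against statsmodels in the
  test suite. Degenerate designs (constant G or G·E after subsetting,
  singular information) are flagged per row, never raised mid-scan.
* Tests: Wald, per the reference analysis (not LRT). The joint test is
  2 df — the reference text says both "one" and "two" degrees of
  freedom in adjacent sentences; the standard joint main+interaction
  Wald test has 2 df and that is what the reported χ² medians imply.
* Exposure coding: binary early indicator by default; continuous AAM
  via `ScanConfig.exposure_coding`. The reference analysis does not
  print its coding; the binary contrast matches its headline results.
* Genomic control: λ = median(stat)/median(χ²_df), df-specific divisors
  0.4549364 (1 df) and 2·ln 2 (2 df), requiring ≥ 100 finite statistics.
  If λ_int > 1.05 for a quantitative trait the scan re-runs on the
  inverse-normal transformed (INT) trait — Blom offsets (r − ⅜)/(n + ¼),
  average ranks for ties, missing preserved — with covariates retained
  in the model, which is how the reference analysis handled its TG
  inflation; dividing the statistics by λ is available as an
  alternative (`gc_action="divide"`). Both λ sets are reported.
* Multiplicity: Bonferroni α/m, and BH step-up q-values (statsmodels).

## Pathway enrichment

The reference analysis cites an "improved GSEA" without printing its
statistic; the choices here are this package's own:

* gene score = max over the gene's SNPs of −log₁₀ p_int (SNPs mapped to
  genes within 20 kb, boundaries inclusive; a SNP may serve several
  genes, with no apportioning);
* pathways retained when their count of genes **with mapped SNPs** is
  in [20, 200] (both ends inclusive, per the printed strict
  inequalities "<20" / ">200");
* weighted KS running sum with weight exponent 1: hits add
  score/Σ(member scores), misses subtract 1/(N − N_H); ES is the signed
  value at maximal |deviation|;
* null by size-matched **gene-label** permutation on the fixed ranked
  list. Phenotype permutation would require re-running the genome-wide
  scan per permutation; at 1,000 permutations that is ~10³ times the
  scan cost and is not built in.
* NES = ES / mean(|null ES| of the same sign); nominal
  p = (1 + #{null ≥ observed, same sign})/(k + 1) (so p ≥ 1/(k+1));
  FDR q GSEA-style from the pooled null NES, clamped to (0, 1].
* "Significant genes" in the report = genes with best-SNP p_int < 0.001
  (configurable); the reference tables use an unstated threshold, and
  their pathway-level abstract quotes "all nominal P < 0.001".

## Synthetic-data generator

One integer seed drives four documented RNG substreams (cohort →
genotypes → missingness → annotation), making every artifact
byte-reproducible. Defaults emulate the reference cohort:

* AAM category probabilities = the published per-category proportions
  (2.4 / 8.5 / 16.7 / 21.0 / 21.7 / 29.7 %); integer years uniform
  within the pooled bins (no within-bin distribution is published).
* Age ~ Normal(56.07, 8.88) truncated to [40, 69]. CRP lognormal
  moment-matched to 1.41 ± 1.30 mg/dl. Covariate marginals (area,
  income, education, smoking, alcohol, OBS) from the published
  descriptive table. The **joint** covariate dependence (e.g., the
  real income/education/area gradients across AAM) is *not* modelled —
  only marginal scales are reproduced.
* TG = 130 + 37.83·1[AAM ≤ 12] + Normal(0, 80) mg/dl by default (the
  reference analysis publishes the early-menarche shift but not the TG
  mean/SD; 130 ± 80 is a realistic right-of-centre scale for this
  population, used additively per the linear model). Other MetS
  component traits are drawn independent of AAM at realistic marginals
  chosen to give ~30% MetS prevalence; the reference analysis found no
  significant non-TG component associations.
* Genotypes: MAF ~ Uniform(maf_range), dosages ~ Binomial(2, MAF) (HWE),
  independent across SNPs — **no LD**, matching the single-SNP model,
  so the synthetic experiments say nothing about LD-induced redundancy.
  Missingness independent at rate 0.002 by default (below the QC cutoff).
  SNPs sit on a regular grid over 22 autosome labels.
* Planted effects add β_main·G + β_int·G·E to TG. `interaction_beta_for_z`
  converts a target Wald z into β_int analytically, including a
  self-consistency correction for the residual variance that multiple
  simultaneously planted SNPs add (each SNP's fit absorbs only its own
  term; the other terms inflate σ² by p_E·(K−1)·β²·Var(G)).
* Annotation: genes tile consecutive same-chromosome SNPs (3 per gene
  by default), pathways are random gene subsets with sizes in [20, 60];
  an optional enriched pathway is guaranteed to contain the genes
  hosting every planted SNP.

## Calibration experiments and the small-exposed-group effect

The cohort-realistic early-menarche prevalence (2.4%) makes genome-wide
calibration checks structurally unstable: with only ~48 exposed women in
a 2,000-woman cohort, *every* SNP's interaction statistic conditions on
the same 48 residuals, so the single-run inflation factor is distributed
roughly 1 ± √(2/48) ≈ 0.2 even for an exactly calibrated test (measured
range 0.63–1.51 over 15 cohorts). This is the same finite-exposed-group
phenomenon that produces real interaction-scan inflation (the reference
scan reported λ_int = 1.32 for TG) and is precisely what the INT-based
genomic control exists to absorb. The calibration and power experiments
therefore use a **balanced exposure mix** (early ≈ 50%), the canonical
design for validating test calibration, under which λ and the type-I
error concentrate at their nominal values; with balanced groups the
interaction contrast is also variance-robust to exposure-specific
heteroscedasticity (its model-based and true variances coincide when
n₁ = n₀). Passing these checks demonstrates the statistics are computed
correctly; it does **not** demonstrate that single-cohort λ is stable at
a 2.4% exposure — it is not, by design of nature. A related visible
effect: planting many large G×E terms inflates σ̂² for every other SNP,
which deflates main-effect z-scores (and hence the 2-df λ) in power-
experiment runs while leaving the balanced interaction test calibrated.

## Problem sizes and numerics

Experiments run at desk scale, chosen so the full suite completes in a
few minutes: null calibration n = 2,000 × m = 5,000 (one seed);
β_int CI coverage over 50 replicate cohorts (n = 2,000, MAF 0.3);
TG-shift and MetS-OR recovery averaged over 20 replicate cohorts of
10,000 (single-cohort estimates scatter ± ~5 mg/dl / ± ~0.2 log-odds at
2.4% exposure); enrichment power over 20 replicates (n = 2,000,
m = 3,000, 30 planted SNPs at realized z ≈ 5, 1,000 permutations);
pathway-null uniformity over 120 gene sets at 300 permutations.
Numerical details: IRLS tolerance 1e-8 with a linear-predictor clamp at
±30; OLS "constant trait" degeneracy flagged at residual variance
< 1e-12; p-values written in scientific notation with 4 significant
digits and "." for missing; ES tie between equal positive and negative
deviations resolves toward the positive (first argmax of |running sum|).

## Known limitations

No LD, population structure, relatedness, X-chromosome handling,
imputation, or mixed models; gene-label (not phenotype) permutation for
enrichment; marginal-only covariate realism in the generator; the
published reference estimates from the restricted cohort are recovery
targets for planted effects on synthetic data, not reproduction targets.
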