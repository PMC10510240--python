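# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the numerical choices, and the known limitations.

## Study design being modelled

A cohort of ~800 individuals of predominantly African genetic ancestry is
measured for genome-wide genotypes and blood DNA methylation on two array
platforms (450K, N=423; EPIC, N=388), with a binary exposure (prevalence
0.361) and clinical covariates. The analysis chain is: genotype-based
ancestry assignment against a labelled reference panel; selection of
exposure-associated candidate CpGs by EWAS with meta-analysis across the
two arrays; cis-meQTL mapping for the candidates; pleiotropy screening of
the index meQTLs (PheWAS lookup plus trait enrichment); and two-sample
Mendelian randomization treating the exposure as the risk factor and
externally GWAS-summarised traits as outcomes.

## Ancestry

* **LD pruning** — greedy left-to-right scan; a variant is dropped when
  its squared dosage correlation with any retained variant within a
  50-variant trailing window exceeds r² = 0.02. Monomorphic variants have
  undefined r² and are retained.
* **PCA** — reference variants centred and scaled to unit variance by the
  reference mean/SD; query samples are projected onto the reference
  loadings. Missing dosages are mean-imputed per variant. Component signs
  follow the largest-magnitude-loading-positive convention so results are
  reproducible across runs.
* **Supervised admixture (K=4)** — with reference allele frequencies held
  fixed, each sample's proportions maximise the binomial admixture
  log-likelihood Σⱼ[gⱼ log(Σₖ qₖ pₖⱼ) + (2−gⱼ) log(Σₖ qₖ(1−pₖⱼ))] by EM on
  the simplex (likelihood non-decreasing; convergence when the gain drops
  below 1e-6, cap 1000 iterations with a warning). Supervised estimation
  is used because the reference panel defines the ancestral groups; it is
  deterministic and fast at cohort scale. Near the simplex boundary EM
  converges slowly, so the iteration cap is routinely hit for
  effectively-pure samples; the returned iterate is accurate to ~1e-3.
* **Admixed detection** — samples whose minimal Euclidean distance to the
  reference-population centroids on PC1–PC3 exceeds the 99th percentile of
  within-class reference distances are flagged. The cutoff is data-driven;
  no magic constant.
* **Classification** — flagged samples keep the ADMIXED label; remaining
  samples are assigned by k=20 nearest neighbours in the standardized
  14-dimensional feature space (10 PCs + 4 admixture proportions), with a
  seeded random subset of 20 flagged samples serving as the ADMIXED
  training class. Ties break by smallest mean neighbour distance.

## EWAS

Stage 1 regresses each CpG's M-value on the technical covariates
(clinical variables, cell proportions, 20 control-probe PCs) *without*
the exposure; the top 5 PCs of the residual matrix capture remaining
batch structure. Excluding the exposure from stage 1 prevents the
residual PCs from absorbing the signal of interest. Stage 2 adds the
exposure and the residual PCs; the exposure coefficient is tested
two-sided against the t distribution with residual degrees of freedom
(exact at these sample sizes, unlike the normal approximation).

Cell proportions come from reference-based deconvolution: constrained
least squares min‖m − Pw‖² with w ≥ 0 and Σw ≤ 1 over the 6 blood cell
types, solved by SLSQP (the problem is a 6-variable QP; tolerance 1e-10).
The last cell type is omitted from the regression design to avoid
near-collinearity with the intercept.

The M-value transform is M = log2(β/(1−β)) with β clamped to
[1e-6, 1−1e-6]. Meta-analysis is fixed-effects inverse-variance
(wᵢ = 1/seᵢ²; se_meta = 1/√Σwᵢ; normal p). Candidates: meta p < 1e-4.
Genomic inflation λ is the median association χ²₁ divided by 0.4549.

## cis-meQTL

Variant QC removes MAF < 0.05 (kept at equality), missing rate > 0.05,
and HWE χ²₁ p < 1e-6 (monomorphic sites p = 1 by convention). Cis pairs
are same-chromosome with |pos difference| ≤ 500 kb, inclusive. The
per-pair fit residualises M and dosage on the covariates once
(Frisch–Waugh–Lovell) and reduces each pair to a simple regression whose
coefficient, SE and p are identical to the joint OLS fit at
df = n − k − 2; this makes the scan linear in the number of pairs.
Missing dosages are mean-imputed inside the fit only, keeping per-pair n
constant. The meQTL covariate design omits the 5 residual PCs by default
(flag `include_residual_pcs` restores them), matching the narrower
covariate list conventional for meQTL scans.

BH-FDR is applied once across all meta-analysed pairs (a single family).
Clumping is greedy per CpG: smallest-p unassigned variant becomes an
index; unassigned variants with in-sample dosage r² > 0.1 join it; p-ties
break by lower genomic position. Nearest-gene annotation assigns
contained positions to their gene (class `genic`) and others to the
minimal-distance gene (`intergenic`), ties to the lower-coordinate gene.

## Pleiotropy

The PheWAS screen restricts to index meQTLs with meta p < 5e-8, collects
catalog rows at p < 0.05 for those variants, and keeps rows passing
α/(n_selected_variants × n_studies), both counts recomputed from the
inputs (with 62 variants and 4,756 studies this threshold is 1.70e-7).
Trait enrichment builds, per trait, the 2×2 table over the tested-variant
universe T with meQTL set M and risk set R (intersected with T; overlap
MR) and tests one-sided for enrichment. The one-sided Fisher p is the
hypergeometric upper tail P(X ≥ MR), computed directly from that
identity; the odds ratio is ad/bc (infinite when bc = 0, undefined and
flagged when a margin is empty). One-sided is the default because the
question is specifically over-representation; a two-sided flag exists.
Trait labels from the two screens are matched exactly after lowercasing
and whitespace normalisation.

## Mendelian randomization

Exposure-side effects come from a *linear* regression of the 0/1 exposure
on dosage, reproducing the field-standard PLINK-style linear fit on a
binary trait; the coefficient is a per-allele risk difference, not a
log-odds ratio, and the causal estimates inherit that scale. Instruments
are restricted to clump indices so they are LD-independent. Harmonization
flips the outcome beta when the allele pair is swapped and drops
strand-ambiguous (A/T, C/G) variants.

* **IVW** — fixed-effect weighted regression through the origin;
  se = 1/√(Σwβ̂ₓ²). A multiplicative random-effects rescaling is
  available via flag but is not the default.
* **Weighted median** — Wald ratios weighted by β̂ₓ²/se_y² (the
  leading-order inverse variance of the ratio); the estimate interpolates
  where cumulative normalized weight crosses 0.5; SE by parametric
  bootstrap (default 1000 draws of β̂ₓ, β̂_y from their normals).
* **MR-PRESSO** — observed RSS is the sum of weighted squared
  leave-one-out residuals; the null distribution simulates outcome betas
  around the leave-one-out predictions (with exposure betas also
  resampled); global p is the empirical exceedance with a +1 correction.
  Per-variant outlier p-values are Bonferroni-corrected across variants;
  note the minimum attainable empirical p is 1/(n_sim+1), so n_sim must
  exceed n_variants/α for the outlier test to have any power (the default
  n_sim = 1000 is exactly sufficient for 30 instruments at α = 0.05).
  The reported estimate is IVW on the outlier-free set; the distortion
  test is informational only.

Family-wise correction: p < α/(n trait-study pairs × 3 methods).

## Synthetic-data model

Genotypes: ancestral allele frequency p₀ ~ Uniform(0.05, 0.5) per LD
block; population frequencies drift as Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)
with F = 0.1 (Balding–Nichols). LD is block-exchangeable: variants within
a 10-variant block share their frequency, and each haplotype copies a
block-level template with probability √r, making the expected
within-block dosage correlation exactly r (default 0.7). The reference
panel (200/population) carries the same block LD as the cohort, as a real
shared panel would. The cohort is 811 samples: ~90% near-pure AFR (a few
percent residual ancestry) and ~10% admixed (Dirichlet(2,2,1,1)).

Exposure: logistic in the planted SNP effects (30 variants, log-OR 0.4
each), intercept tuned numerically to prevalence 0.361.

Methylome: M = cell mixture (Dirichlet proportions × reference profiles)
+ cis effects (50 variant–CpG pairs at 0.5 per allele, planted on
exposure-associated CpGs and on distinct LD blocks, restricted to
variants common in the study population so the planted truth survives
MAF QC) + exposure effects (60 CpGs at 0.5) + small age/tobacco effects
on 10% of CpGs + per-cohort batch shift + a technical factor that also
drives the control probes + five hidden batch factors that drive the
methylome but *not* the control probes + N(0, 0.5) noise. The hidden
factors exist because the two-stage procedure computes residual PCs
precisely to capture such structure; without them, at scaled-down CpG
counts the exposure itself would become a top residual PC and the
procedure would remove its own signal — an artifact of scale, not of the
method.

Outcome GWAS: an independent cohort of 5,000 with the same allele
frequencies and LD; outcome = γ·exposure + direct pleiotropic effects +
N(0,1), summarised by per-variant marginal OLS. Default γ = 0.3 for all
three overlap traits; one trait carries a single variant with a direct
effect of 1.0 (the planted MR-PRESSO outlier).

Catalog: enriched traits draw their 40 risk variants from the true-meQTL
LD blocks at 5× the background rate (null traits draw uniformly, making
the enrichment null exactly hypergeometric); enriched-trait rows carry
very small p-values so the same traits surface in the PheWAS screen.

Problem sizes (2,000 SNPs over 4×10 Mb chromosomes, 1,000 CpGs, cohorts
423+388, outcome n=5,000) keep a full pipeline run around a minute on one
CPU while preserving every structural feature the stages consume. What
the generator does **not** emulate: realistic probe annotation and
Infinium chemistry, coalescent LD and allele-frequency spectra,
imputation uncertainty, cell-type interaction effects, and catalog trait
ontologies. Passing tests therefore validate the statistical machinery
and its calibration, not array-specific preprocessing.

## Numerical and degenerate-input conventions

* Betas clamped to [1e-6, 1−1e-6] before the M transform; p-values
  clamped away from 0 at the smallest positive double.
* Monomorphic variants: r² treated as 0 in pruning; HWE p = 1; meQTL
  records emitted with p = 1 and a `degenerate` flag.
* Sample alignment between genotype, methylation and covariate tables is
  verified on ordered ids at every stage; mismatch is an error, never a
  silent reindex. Subsetting is always explicit.
* PCA/SVD signs fixed by the largest-|loading|-positive rule; KNN and
  clumping ties broken deterministically (mean neighbour distance; lower
  genomic position).
* Every stochastic routine takes a seed; stage outputs are byte-identical
  across reruns with the same seed.

## Known limitations

* Weak-instrument attenuation: with per-instrument exposure associations
  around z ≈ 3.5 and selection at p < 0.05, the IVW estimate is
  attenuated by roughly 10–20% (regression dilution in β̂ₓ plus winner's
  curse). This is a property of the estimator under these study
  conditions, visible in the recovery experiments, and would equally
  affect the real analysis.
* The exposure-side linear fit on a binary trait makes the causal
  estimate scale-dependent; estimates are reported in native per-allele
  units without standardisation.
* The Fisher enrichment test is exact and therefore conservative; its
  attainable size at α = 0.05 is ~0.04 at the default margins.
* Unsupervised admixture, local ancestry, trans-meQTLs, MR-Egger and
  multivariable MR are out of scope.
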