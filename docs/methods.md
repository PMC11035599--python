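# Methods

## Scope and model

`partprs` analyses the association between compartment-restricted polygenic
scores for a discovery trait ("the disorder") and continuous brain
phenotypes (white-matter tract metrics), and cross-checks the score-level
findings with block-wise local genetic correlation computed directly from
summary statistics. The package operates downstream of genotype calling and
imaging-derived phenotype extraction: inputs are a discovery-GWAS
summary-statistics table, target-cohort diploid dosages, gene models, gene
sets, and per-participant covariate/phenotype tables.

## Variant QC and compartments

Variants are dropped when the minor-allele frequency is below 5% (strict) or
the Hardy–Weinberg exact-test p-value is below 10⁻⁶ (strict). The HWE test
conditions on the observed allele counts and sums the probabilities of all
heterozygote counts no more probable than the observed one (two-sided exact
test); it is validated against an exact-rational full-enumeration oracle for
every genotype configuration with n ≤ 20.

A variant is **genic** when it falls within the extended window of any gene:
35 kb upstream and 10 kb downstream of the gene body by default. Upstream
and downstream are only meaningful relative to transcription direction, so
the window is strand-aware (a minus-strand gene is windowed 10 kb before its
start coordinate and 35 kb past its end); a `strand_aware=False` switch
windows every gene as if plus-strand, since annotation conventions differ
between pipelines. Window membership is inclusive at both ends, matching the
coordinate arithmetic of the boundary cases in the test suite. Gene-set
membership uses the same windows restricted to set genes, so set membership
implies genic. Region masks (e.g. `MHC=chr6:25000000-35000000`) are
half-open `[start, end)` on position; masked variants keep their
genic/intergenic label and are excluded only from the `-MHC` score variants.

## Harmonization

Summary statistics are matched to target variants on (chromosome, position)
— synthetic variant ids are arbitrary, and positional matching is what
survives id-scheme changes. When the effect allele equals alt the weight is
the reported per-allele effect; when it equals ref the sign is flipped;
other allele pairs are dropped. Palindromic (A/T, C/G) pairs are
strand-unresolvable by letters alone: they are dropped when the reported
effect-allele frequency lies in (0.4, 0.6) and otherwise oriented by which
target allele frequency the report is closer to. This is standard PRS
practice; the trade-off is a small loss of variants against protection from
silent sign errors.

## Clumping and scoring

LD is the squared Pearson correlation of dosage columns in the target cohort
itself (no external panel — the same cohort provides genotypes and LD).
Clumping sorts candidates by ranking p-value (ties broken by genomic
position for determinism), repeatedly takes the best unremoved variant as an
index and removes unprocessed same-chromosome neighbours within 1 Mb
(inclusive) with r² strictly above 0.1 — pairs at exactly the threshold are
retained. Clumping always runs *within* the compartment being scored, so an
index retained in the genic set may remain in high LD with an index retained
in the intergenic set; the test suite asserts this is possible, because it
is a property of the within-set semantics rather than a defect.

A raw score is Σ wⱼgᵢⱼ over retained variants passing the p-threshold
(10⁻⁵, 10⁻⁴, 10⁻³, 0.01, 0.1). Missing dosages are mean-imputed at read
time, so they contribute the variant mean. Scores are residualized on the
first 15 principal components plus a genotyping-array indicator and
z-scored; constant covariate columns are dropped, remaining collinearity is
an error naming the offending columns, and a zero-variance residual (score
fully explained by covariates) is an error rather than a silent zero column.
Few-SNP "added-risk" scores are GWAS-weighted sums by default; an
`allele_count` mode counts risk alleles (recoding 2−g when the oriented
weight is negative) for single-SNP analyses. Per-gene scores clump within
the gene's window and use the most inclusive threshold (0.1) by default,
exposed as a parameter since reasonable analyses differ here.

## Phenotype preparation

Each hemisphere × measure column is screened once (not iterated) for values
strictly beyond 3 SD of the column mean; a participant flagged in any
hemisphere or measure of a tract is excluded for that whole tract, and
surviving left/right values are averaged. Trimming precedes averaging
because an artifactual hemisphere corrupts the mean. Under normality the
expected exclusion rate per column is ≈ 0.27%, which the tests verify by
Monte-Carlo.

## Association models

Each model is OLS of a standardized phenotype on one or more standardized
scores plus sex, age (linear) and scan site (categorical dummies).
Standardization is computed on the post-listwise-deletion analysis sample.
Reported are standardized betas, SEs and two-tailed t p-values; with several
scores entered jointly each beta is conditional on the others. Multiple
testing uses Bonferroni families mirroring the analysis tables — e.g. a
5-threshold × 4-tract table is one family of 20 (threshold 0.0025), a
3-compartment masked table is 60 (threshold 0.00083), the per-autosome scan
is a single family across autosome × tract tests. The per-autosome scan
scores the intergenic compartment per chromosome at the 10⁻⁴ threshold, with
an extra region-masked column for the chromosome carrying the mask;
chromosomes with no qualifying SNPs are skipped with a log message.

## Local genetic correlation

The genome is tiled into quasi-independent blocks (uniform 1 Mb by default,
or a user block table; a merge directive collapses a named region's blocks
into one). Within a block with LD matrix R (from reference genotypes,
eigendecomposed and truncated at 99% cumulative eigenvalue mass, k retained
components), standardized marginal effects b are projected as
αⱼ = uⱼᵀb/√λⱼ. Under the null the αⱼ are i.i.d. N(0, 1/n), so

- local h² = Σαⱼ² − k/n (method of moments), with the p-value from the
  exact null n·Σαⱼ² ~ χ²ₖ. A parametric-simulation p-value is available but
  cannot resolve below 1/(n_sim+1), which a Bonferroni screen over thousands
  of blocks requires; the analytic form is the same null distribution the
  simulation draws from.
- bivariate local covariance = Σαⱼᴬαⱼᴮ with no noise correction, valid for
  non-overlapping GWAS samples (declaring overlap is an error; no
  sampling-covariance correction is implemented);
  r_g = cov/√(h²ᴬh²ᴮ) truncated to [−1, 1]. The p-value tests zero local
  covariance by parametric simulation preserving each trait's per-component
  magnitude; the CI is a percentile parametric bootstrap under a
  homogeneous-per-component bivariate-normal approximation.

Standardized marginal effects are obtained by harmonizing the summary
statistics against the reference panel and multiplying the oriented
per-allele weight by the dosage SD — not by reconstructing z from p, which
saturates at floating-point p-value floors and breaks the LD consistency of
the marginal vector on high-LD blocks.

Blocks where *both* traits pass the univariate screen at 0.05/m (m = number
of blocks) proceed to the bivariate test, which is then
Bonferroni-corrected over the tested blocks. This estimator is a deliberate
simplification of full local-correlation machinery: no conditional or
multivariate models, no binary-trait liability conversion, no
sample-overlap correction.

## Synthetic cohort

The generator produces every input the pipeline consumes, with a planted,
fully known architecture.

**Genotypes.** Per block, two latent haplotype chains follow a
non-stationary AR(1); each variant's allele is the indicator of its latent
value falling below the MAF quantile, and the dosage is the sum of the two
haplotypes (so HWE holds by construction). The adjacent-pair latent
correlation is calibrated by tetrachoric inversion (Brent root-finding on
the bivariate normal CDF, cached) so the **dosage** correlation hits the
requested target r² — thresholding attenuates latent correlation, so using
the target as the AR(1) parameter directly would undershoot. Correlation
decays multiplicatively with SNP distance and is zero across blocks. MAFs
are drawn around a per-block centre (jitter ±0.02) within the configured
range, because strongly unequal margins cap the attainable binary
correlation well below high LD targets; LD partners sharing similar MAF is
also what real data look like. Defaults: 4 chromosomes × 20 Mb, 1 Mb
blocks, 8 SNPs/block, adjacent r² 0.4 genome-wide and 0.8 inside the
designated region (chr2:5–15 Mb) — a miniature of a genome with one
MHC-like high-LD stretch.

**Annotation.** One gene per even-indexed block (30–55% span, alternating
strand); the gene set contains the first three genes inside the designated
region plus one outside gene, mirroring a pathway nested in, but not
confined to, the region.

**Effects.** Point-normal: each variant is causal with probability
`prop_causal`, multiplied by `set_enrichment` (capped at 1) for gene-set
variants. Causal effects for the discovery trait and each tract are
bivariate normal with correlation `rho_traits` (default −0.9: risk alleles
reduce the tract metric), rescaled so the realized variance of the regional
and background genetic components equal `h2_region` (0.02) and
`h2_background` (0.10) exactly in-sample. The discovery trait shares these
variance targets; no empirical scale for the regional effect exists to
calibrate against, so the magnitudes are free parameters chosen to put the
planted signal near the detection margin at realistic cohort sizes.

**Summary statistics.** Marginal effects are generated analytically as
Rβ + e per block with e ~ N(0, R/n_discovery) — exact control of sampling
noise without simulating a discovery cohort (default n = 100,000). A random
30% of rows report the ref allele as effect allele (sign and frequency
flipped) to exercise harmonization; ref/alt letters avoid palindromic pairs
so the generated files are fully resolvable.

**Phenotypes and covariates.** Axonal density per tract = genetic component
+ sex/age/site effects + Gaussian noise; orientation dispersion carries no
genetic signal (the null measure). Hemisphere values share 95% of the
tract-level variance, so left/right correlate at ~0.95 and the bilateral
pipeline is exercised. Age is uniform on [45, 81]; sex/site/array are
categorical integers; the 15 PCs are pure noise — population structure is
deliberately not modelled, so PC adjustment is exercised as a near-no-op.

**What the generator does not emulate** (and what passing tests therefore do
not show about real data): imputation uncertainty, the X chromosome,
population stratification and relatedness, realistic recombination maps,
indels and structural variation (including copy-number biology of
complement genes), binary discovery traits with case-control ascertainment,
and GWAS sample overlap with the target cohort.

## Study designs used for validation

- **Regional-signal recovery** (`studies.signal_recovery_study`): 20 cohorts
  of n = 20,000 with heritability only in the region's gene set
  (`h2_region=0.03`, background 0, base causal rate 10⁻⁴, set enrichment
  10⁶ so every set variant is causal). Per replicate the pipeline must find
  a Bonferroni-significant association for the gene-set and intergenic
  score families, find none for the region-masked gene-set family, rank the
  gene set above a size-matched null set, and localize the scan signal to
  the region's chromosome. Success is required in ≥ 90% of replicates.
- **Clumping validity**: 200 random instances (≤ 200 variants, planted
  copy-with-corruption LD) checked exhaustively for retained pairs
  violating the r²/window rule, and against an independent re-implementation
  of the greedy trace.
- **Association calibration**: closed-form OLS oracle agreement to 10⁻¹⁰ and
  null type-I error 0.05 ± 0.014 over 1000 replicates of n = 2000.
- **Local r_g**: planted r_g = 0.5 (h² = 0.05, n = 500,000, 20-SNP high-LD
  block) recovered within ±0.1 in the mean of 50 replicates; null local-h²
  rejection rate within 0.05 ± 0.02 over 1000 null blocks; a trait against
  itself returns r_g = 1 exactly.

Problem sizes were chosen so the full suite and the reproduction script
each run in minutes on a single CPU while keeping Monte-Carlo error well
inside the asserted tolerances.

## Numerical choices and edge cases

- Ties in clumping p-values break by (chromosome, position); results are
  independent of input order and participant-row permutation.
- Monomorphic variants: MAF filter removes them before LD; `ld_r2` on a
  monomorphic column is an explicit error rather than NaN.
- Empty score columns (no SNPs past threshold) are emitted as all-missing
  with SNP count 0 and skipped by the association layer with a log message.
- p-values emitted by generators are floored at 10⁻³⁰⁰ to stay inside the
  (0, 1] domain contract.
- Eigenvalues below 10⁻¹⁰ are discarded before the cumulative-variance
  truncation; a block with no usable components is an error.
- The bootstrap covariance matrix for the r_g CI is projected to the
  nearest PSD matrix when the point estimate implies |r_g| ≈ 1.

## Known limitations

The local-correlation estimator is a simplified method-of-moments
procedure; its CIs are approximate and its bivariate p-values are
simulation-bounded. Target-cohort LD is used in place of an external
reference panel, which is correct for the intended single-cohort design but
not for transferring weights across populations. The pipeline assumes
hard-call or lightly imputed dosages; BGEN/PLINK-binary inputs, indels and
build liftover are out of scope.
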