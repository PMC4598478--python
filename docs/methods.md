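# Methods

## The statistical procedure

The phenotype is the OLS residual of mean bilateral amygdala volume on an
intercept, a male indicator and intracranial volume (ICV), computed once on
the analysis sample. Every downstream test uses this residual vector; the
permutation scheme shuffles it directly, which is equivalent to shuffling
raw volumes and re-residualizing, because the covariates travel with the
subject only through the residual.

Per locus, subjects are grouped by genotype class after QC's small-group
merging, and a one-way ANOVA is computed on that locus's complete cases
(group sizes therefore vary across loci). Loci with p < 0.05, uncorrected,
form the candidate set. No multiplicity correction is applied at this
stage by design: family-wise control is delivered wholesale by the
permutation test, and an uncorrected screen keeps type-II error low where
single-locus effects are ~1% of variance.

Candidates are coded additively — 1/2/3 for major homozygote,
heterozygote, minor homozygote; X-linked SNPs 1/3 with female
heterozygotes coded 3 (minor-allele dominance under X inactivation); an
X-linked VNTR codes 1 for the 3-repeat allele (males by their single
allele, females only when 3-repeat homozygous) and 3 otherwise; autosomal
VNTRs code like SNPs. Coding always uses the original three genotype
classes, even where the ANOVA merged small groups.

Forward stepwise regression enters the candidate with the smallest
partial-F p-value while that p < 0.05, and removes entered regressors whose
p rises above 0.10 (classic entry/removal defaults; both are config knobs
and pure forward selection is available). n is fixed before selection by
listwise deletion over the candidate set, so R² is comparable across steps;
mode imputation is available as an alternative. Ties in partial F break by
genomic order. Candidates whose residual variance given the entered set is
numerically zero (relative tolerance 1e-10) are tagged "collinearity" and
never enter. Adjusted R² = 1 − (1−R²)(n−1)/(n−k−1); the overall F is
reported with the conventional (k, n−k−1) degrees of freedom.

## Selection-aware inference

Because screening and stepwise selection are refit to the data, the final
model's F-test is anti-conservative — in our null calibration its rejection
rate at nominal 0.05 is several-fold too high. The model-level p-value is
therefore a *whole-procedure* permutation test: for each of 1000 phenotype
shuffles the screen, the coding and the stepwise selection are re-run from
scratch and the resulting R² recorded. The default p is the paper-literal
strict convention, #{null R² > observed}/n_perm; since a permutation p of
exactly zero is improper, the add-one convention (#{≥}+1)/(n_perm+1) is
always co-reported. Shuffles in which no locus passes the screen score
R² = 0 (required for the null to be well defined); their count is reported.
Genotype-group merge maps are held fixed across shuffles — they depend only
on genotypes, which permutation does not touch.

The bootstrap resamples subjects with replacement (genotype rows and
residuals jointly) and re-runs the whole procedure per resample, giving a
percentile CI for R² and adjusted R². This "honest" CI is typically shifted
*above* the observed R̂²: each resample re-selects its own best loci, which
inflates resampled R² exactly as the original selection inflated the
estimate. A fixed-model variant (refit only the observed model's loci per
resample) is available; it brackets the point estimate but understates
selection uncertainty. Both are reported by the example scripts so the
contrast is visible.

Randomness: one root seed; per-iteration generators are spawned from a
`SeedSequence` by counter, so results are independent of execution order
and bit-reproducible.

## QC details and conventions

- Stage order: quality masking → sample-missingness filter → grouping →
  HWE → LD pruning → relatedness. Genotype-level and sample-level
  exclusions are thereby reported separately.
- All threshold comparisons are strict in the stated direction: quality
  exactly 0.25 is retained; a subject missing exactly 10% is retained; an
  LD pair at exactly r² = 0.8 is retained.
- Major/minor alleles come from post-masking sample frequencies; an exact
  50% tie resolves to the lexicographically later label as minor, for
  determinism.
- HWE is flag-only by default (deviating loci are retained, as selection
  effects rather than genotyping error can produce deviation in a
  homogeneous volunteer sample); exclusion is available by config. X loci
  use females only.
- LD r² is the composite (genotype-dosage correlation) estimator over
  complete pairs, not EM haplotype r² — deterministic, genotype-level, and
  standard for pruning. The greedy scan runs in genomic order and keeps the
  earlier-position member of a high-LD pair.
- Relatedness: method-of-moments IBD from IBS counts with expected-IBS
  weights from sample allele frequencies, probabilities clamped to [0,1]
  and renormalized, PI_HAT = P(IBD=1)/2 + P(IBD=2). No finite-sample
  bias-correction factors are applied; with panels of several hundred
  independent markers the estimator is sharp (duplicates ≈ 1,
  parent–offspring ≈ 0.5, unrelated ≈ 0), while on a ~90-locus LD-bound
  panel PI_HAT is noisy and the ≥ 0.5 flags are tail noise — pairs are
  flagged, never auto-removed, and a `protocol_threshold` (default 0.95)
  is echoed into the report for audit.

## The synthetic-study generator

The generator emulates the study design the pipeline targets: 417 subjects
(179 male, 238 female), 99 markers (six X-linked, one MAOA-style VNTR) in
LD blocks of three, a handful of blocks in near-perfect LD (r² ≈ 0.97) so
pruning has work, sex and ICV effects on volume, and five planted additive
effects in distinct blocks.

LD model: within a block, a haplotype is comonotone across loci (all
minor-allele indicators driven by one shared uniform) with probability m
and independent otherwise; m is solved from the target dosage r², capped
at the best-achievable coupling when allele frequencies differ (with a
warning). Random pairing of haplotypes makes Hardy–Weinberg equilibrium
hold by construction; males receive a single X haplotype. A designated
locus can violate HWE by excess-homozygote resampling, for QC tests.
Duplicates copy a subject's haplotypes; a parent–child pair passes one
parental haplotype per block and draws the other fresh (the child is
female so an X transmits cleanly).

Phenotype: volume = 1700 mm³ + 60·I(male) + 7·10⁻⁴·(ICV − mean) + planted
term + N(0, 150²), with ICV log-normal (medians 1.55/1.40 × 10⁶ mm³ by
sex, σ = 0.065). These constants are cosmetic, chosen to put the total SD
near 180 mm³ and the sex/ICV F statistics at the two-digit scale typical
of volumetric covariate screens. Planted betas are rescaled by one common
factor so Var(Σβ·code)/(Var + noise²) equals the 8% target, using
empirical coding variances (`calibrate_effect_sizes`; the closed form
makes β scale linearly in noise_sd). Missingness (0.2%) and low-quality
calls (0.2% below the 0.25 threshold) mirror the array-era rates the QC
rules were written for. BAI/BDI scores are independent Poisson draws —
null by construction, exercising the screen-then-drop covariate path.

What the generator does **not** emulate: realistic human LD maps and
recombination, allele-frequency spectra from ascertainment, population
structure, genotyping batch effects, or phenotype non-normality. Passing
calibration tests therefore demonstrates correctness of the procedure
under its own assumptions, not robustness to those real-data features.

## Numerical choices

- Stepwise is solved on the centered Gram system; each entry step costs a
  single block solve, and partial-F p-values use `scipy.special.fdtrc`
  directly. With identical duplicate columns, which member of the pair
  enters is decided by last-bit BLAS arithmetic — deterministic for a
  given build, and the other member is always tagged collinear.
- The per-locus ANOVA screen inside permutation/bootstrap loops is
  vectorized as sparse group-membership matrix products batched across all
  replicates; bootstrap weighting enters as subject multiplicities, which
  is algebraically identical to ANOVA on the materialized resample (tested
  against that oracle).
- The Lilliefors (estimated-parameters) KS p-value comes from a seeded
  Monte Carlo null table, 10⁴ draws by default, cached per sample size;
  the add-one convention keeps p > 0. Published table approximations
  (statsmodels) agree to within a few hundredths.
- An ANOVA cell with zero within-group variance but real between-group
  spread reports p = 0; monomorphic or single-group loci are "untestable"
  and never pass the screen.

## Problem sizes used in the test suite

Calibration tests run 200 null studies and 100 planted-signal studies at
the full 417 × 99 design with 199 permutations each, sizes at which the
binomial bands in the assertions are meaningful while the suite stays in
the low minutes; the relatedness screen is skipped inside these loops (it
does not feed the inference chain). The acceptance script runs the
complete design once with 1000 permutations and 1000 bootstraps.

## Known limitations

- Only biallelic markers; no imputation, no phased haplotypes, no
  epistasis or haplotype models.
- The honest bootstrap CI inherits the selection bias of the statistic it
  resamples; it is a CI for "R² as this procedure measures it", not for
  the population gene-set R².
- PI_HAT on small LD-bound panels is indicative only (see above).
- The Lilliefors table is Monte Carlo, so its p has ~1/√n_mc resolution.
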