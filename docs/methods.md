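# Methods

This note documents the models, parameter choices, numerical details, and
known limitations of the package. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Synthetic cohort generator (`simpop`)

The generator emulates a household-survey cohort from a recently admixed,
EUR-predominant urban population, genotyped on a SNP array alongside a
public reference panel.

**Ancestral allele frequencies.** Balding–Nichols: a common ancestral
frequency p ~ Uniform(0.05, 0.95) per variant, then per population
p_a ~ Beta(p(1−F_a)/F_a, (1−p)(1−F_a)/F_a), so Var(p_a) = F_a·p(1−p).
Defaults F = (0.15, 0.16, 0.12, 0.11) for AFR/EUR/AMR/EAS approximate
continental-superpopulation differentiation. F = 0 is handled as the
limit p_a = p.

**Global proportions.** q ~ Dirichlet(α) with α = 10·(0.194, 0.714, 0.071,
0.020); the mean is the stated (0.70, 0.19, 0.07, 0.02) EUR/AFR/AMR/EAS
vector normalized onto the simplex (its raw form sums to 0.98).

**Tract mosaic.** Per haplotype and chromosome, breakpoints follow a Poisson
process at rate g per Morgan (default g = 10 generations since admixture)
and each segment's ancestry is drawn i.i.d. from q. Breakpoints joining
same-ancestry segments are invisible, so the effective switch rate is
g·(1 − Σ_a q_a²). This is the simplest process with exponential tract
lengths; it ignores the pedigree structure of recombination within the
admixture graph.

**Genotypes.** Each haplotype allele is Bernoulli(p_a) at its local
ancestry a; diploid calls are haplotype sums, so truth phase is exact.
There is no LD within ancestral populations, no post-admixture drift, and
no mutation; genotyping error is limited to an optional uniform missingness
rate (default 0). Allele pairs are drawn among non-palindromic combinations,
as in array design; palindromic handling in QC is exercised by explicit
fixtures instead.

**Households.** The default plan is 60 singletons, 30 couples, and 60 trios
(300 individuals, 150 households). Couples are genetically independent
founders; trio children are produced by meiosis — crossovers at 1 per
Morgan per gamete, source haplotype alternating from a random start — which
splices both the allele vectors and the truth tracts, so a child's truth q
is the mean of its two transmitted-haplotype ancestry fractions.

**Reference panel.** 400 unadmixed individuals per population (the scale of
a public-catalog superpopulation panel), in Hardy–Weinberg proportions
within each population.

**Self-report.** Category utilities are linear in (1, q_AFR, q_EUR, q_AMR)
plus Gaussian noise (scale 0.5); the argmax of
{Black, Mixed, White, Indigenous, Yellow} is reported, with a 1.3%
nonresponse rate. Coefficients were calibrated once so that (i) category
shares are realistic for the emulated population (≈50% White, ≈39% Mixed,
≈9% Black, traces of Yellow/Indigenous) and (ii) self-reported category
explains roughly a third of the median-regression variation in African
ancestry (pseudo-R² ≈ 0.35). Passing tests therefore show internal
consistency of the pipeline under this model, not that real self-report
behaves this way; in particular the generator cannot reproduce the heavy
right tail of African ancestry seen in real admixed cohorts, because the
Dirichlet concentration of 10 keeps q relatively tight around its mean.

**Determinism.** One `numpy` Generator seeded from `SimConfig.seed` drives
every draw; identical seeds give bit-identical cohorts, truth, and files.

## QC (`qc`)

Cascade order: sample call rate → marker exclusions (non-rs id when
flagged, sex chromosomes, palindromic A/T–C/G pairs, region mask) → MAF →
Hardy–Weinberg → LD pruning → panel merge. Two presets mirror the two
passes of a typical analysis: `grm` (MAF < 0.05, r² 0.5) and `pca`
(MAF < 1e-4, r² 0.2); both use call rate ≥ 0.95, HWE p ≥ 1e-6, and
windows of 50 SNPs advancing by 5.

- *HWE*: plain Levene–Haldane exact test (no mid-p), two-sided by
  probability mass, computed with the stable recurrence on the conditional
  het-count distribution; monomorphic sites return p = 1. Tests verify
  agreement with an independent log-factorial enumeration to 1e-12 for all
  n ≤ 200 tables sampled.
- *LD r²*: squared Pearson correlation of dosages over pairwise-complete
  samples (composite LD, no phasing). Within a window, the first offending
  pair in scan order loses its lower-MAF member; ties remove the later
  position. Pair r² values do not change when other variants are removed,
  so each window's correlation matrix is computed once.
- *Region mask*: defaults to the extended MHC (chr6:25–35 Mb, GRCh37-style
  labels), standing in for published long-range-LD masks; fully
  configurable.
- *Merge*: variants intersect by id; alleles must match directly, by
  ref/alt swap (dosage flipped d → 2−d), by strand complement, or both;
  multiallelic records and mismatches are dropped with reason codes.

## Relatedness (`relate`)

GRM in the standard allele-frequency-standardized form with missing calls
imputed to 2p (zero contribution), divided by the number of polymorphic
markers. Expected relatedness halves per degree: 2K = (1/2)^degree, so the
second-degree exclusion threshold is K = 0.125. Exclusion operates on
estimated kinship K = A_jk/2 by default; `threshold_scale="relatedness"`
thresholds A_jk itself, since the convention is ambiguous in the field.
Pruning deletes the max-degree node of the close-pair graph repeatedly;
ties prefer deleting non-heads, then the younger, then the
lexicographically larger id, making the kept set deterministic. On default
synthetic cohorts this removes exactly the trio children (60 of 300).

## Global ancestry (`globalanc`)

PCA uses SVD of the standardized matrix; eigenvalues are of the sample
covariance across individuals (ddof N−1); loadings are orthonormal to
1e-8. K = A−1 = 3 components by default — the minimal dimension separating
four vertices. Projection standardizes new samples with the *model's*
means and scales; missing sites contribute zero. No shrinkage correction is
applied to projected scores (a documented limitation: projected relatives'
scores are slightly attenuated toward the origin).

PC-simplex proportions solve non-negative least squares on the
sum-augmented system (weight 1e4·(1+max|c|) on the Σq = 1 row) and
renormalize; degenerate centroid configurations raise an error naming the
closest pair.

Supervised EM uses the standard responsibility update; panel frequencies
are clipped to [1e-6, 1−1e-6]; convergence is max|Δq| < 1e-6 or 2,000
iterations, with per-sample convergence flags (non-convergence is not
fatal). The log-likelihood is non-decreasing by construction and asserted
in tests. EAS is always estimated and reported even where a reporting layer
might hide small components.

Panel homogenization estimates each candidate's q by supervised EM against
leave-self-out frequencies for its own population (closed-form count
adjustment, not a refit of the panel) and keeps candidates with
q_own ≥ 0.95, then recomputes frequencies from the kept set.

Measured recovery at the default scenario (M = 5,000, N = 300, panel
400/pop): supervised-EM RMSE ≈ 0.019 (the infinite-panel limit at this M is
≈ 0.019, so panel noise is no longer the bottleneck); PC-simplex mean
absolute error ≈ 0.016 per component; the two estimators agree within 0.015
on average.

## Local ancestry (`localanc`)

The HMM replaces a random-forest CRF tool: the downstream analysis needs
per-SNP ancestry calls, dosages, and means, which the chain provides with
verifiable dynamics. g is taken from configuration (default 10), not
re-estimated; q comes from the global estimates (uniform if absent);
ε = 0.01 absorbs genotyping error and panel-frequency noise. Chromosomes
are independent chains initialized at q. Forward–backward runs in scaled
(normalized) arithmetic with the log-likelihood accumulated from the
normalizers; Viterbi runs in log space with ties broken toward the previous
state, then the lowest ancestry index.

Tract bounds are placed at the outermost SNP positions of each constant
run (0-based half-open in BED) — not at midpoints between flanking SNPs —
so tracts never extend beyond observed markers.

An unphased fallback (`diploid_posteriors`) runs the paired-state chain
over ordered ancestry pairs (A² states, Binomial emissions); it is slower
and only returns expected dosages. The main path assumes phased input, as
the generator provides truth phase (mirroring the use of statistically
phased data upstream in real analyses).

Measured at F = 0.2, A = 2, g = 10, M = 5,000: Viterbi per-SNP accuracy
≈ 90.4%, increasing monotonically in panel divergence; per-sample
genome-wide mean dosage/2 agrees with global q within 0.05 mean absolute
difference.

## Selection scan (`scanstats`)

Genome-wide SD across SNPs per ancestry (ddof M−1), matching a single pair
of dashed thresholds across the genome; a per-chromosome option exists.
z = 4.42 ⇔ two-sided normal p = 1e-5. No autocorrelation correction is
applied — each locus is treated independently, as in the analysis being
reproduced — so the z-scores are descriptive. Neighboring SNPs share
tracts, giving the mean-ancestry field a correlation length of roughly
1/g Morgans; under the neutral default scenario (N = 500, M = 5,000) a run
is free of 4.42-SD flags with probability ≈ 0.93 (estimated over 120
seeded replicates; excursions, when they occur, are single loci at
|z| ≈ 4.4–4.8). This is ordinary family-wise error over ~10² effective
loci per ancestry, not evidence of selection, and is the reason a
zero-flag expectation does not hold in every replicate.

## Association (`assoc`)

Write-in recoding folds case and diacritics and maps the "moreno/a
(claro/a), moreninho/a" lexicon to Mixed; unknown write-ins become Other
with a warning; empty responses are NotAnswered. Tests restrict to
Black/Mixed/White, the categories with usable counts. Chi-square
(uncorrected) switches to the exact RxC Fisher test when any expected cell
is below 5; the Fisher p is computed by enumeration over tables with fixed
margins (capped at 2e6 tables; denser tables fall back to chi-square,
which is valid there anyway). Kruskal–Wallis compares each ancestry
proportion across categories.

Quartile bins use empirical quartiles of the analyzed sample with ties at
a cut point assigned to the lower bin; percentages round half-up to one
decimal. Quantile regression (statsmodels QuantReg) fits τ = 0.5 and 0.75
with age in integer years; pseudo-R² is Koenker–Machado
(1 − V_fit/V_intercept-only). Confidence intervals default to a seeded
xy-pair bootstrap (1,000 replicates at the function level; the pipeline
uses 200 as its desk-scale default); kernel-based asymptotic intervals are
available, rank-inversion is not. Collinear designs raise an error naming
an offending column.

## Pipeline (`pipeline`, `cli`)

`run_all` executes simulate → QC(grm) → GRM/pruning → QC(pca) → merge →
panel homogenization → PCA fit + projection of relatives → global q (both
estimators) → HMM local ancestry → scan → association, writing TSV/BED per
stage plus `manifest.json` (seed, version, per-stage counts and timings).
Reruns with one seed are byte-identical; an existing run directory is not
overwritten without `force`. The default configuration completes in about
3–4 minutes on one CPU.

## Problem sizes used in tests

Unit tests run on reduced scenarios (hundreds of markers, tens of
samples); recovery and calibration checks use the default M = 5,000
scenario shared across the suite via session fixtures; the null-calibration
experiment uses 20 seeded N = 500 cohorts scanned on truth dosages. These
sizes are the package's chosen desk-scale study conditions.
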