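# Methods

## The model

`aberrex` detects *aberrant* gene expression at two levels of a
population-scale expression matrix **E** (genes × individuals):

1. **Gene sets that tend (or tend not) to be aberrantly expressed.**  For a
   gene set of m genes measured in n individuals, the per-individual
   Mahalanobis distance to the population centre is

       MD_i = sqrt( (x_i − μ)ᵀ Σ⁻¹ (x_i − μ) ),

   where x_i is individual i's m-vector of set-gene expression and (μ, Σ)
   are a robust location and m×m gene–gene scatter.  The set-level
   statistic is SSMD = Σ_i MD_i² — squaring up-weights the extreme
   individuals.  A set's SSMD is compared with a permutation null built by
   drawing m random genes from the full matrix (which destroys the
   correlation structure between set genes) and re-running the entire
   robust-distance pipeline.  A set is class **L** (aberrance-prone) when
   its SSMD exceeds the null at the Bonferroni-corrected level, class **S**
   when it falls below, otherwise neutral.

2. **Outlier individuals within an L set.**  Squared distances of
   multivariate-normal data follow χ²_m, so the ranked MD² values are
   plotted against χ² quantiles at p = (i − 0.5)/I; individuals beyond the
   χ²(0.975, m) quantile of squared distance are called outliers (a "gap"
   variant additionally requires them to sit beyond the largest break in
   the ranked tail).

Downstream modules ask what distinguishes aberrance-prone genes and outlier
individuals: a two-population difference statistic, twin discordance,
common-eQTL effect sizes, and private-variant enrichment (below).

## Robust estimation

Location and scatter come from the minimum covariance determinant (MCD)
estimator (`sklearn.covariance.MinCovDet`, consistency-corrected and
reweighted), with support fraction (n + m + 1)/2n by default.  Robustness
matters because the outliers we want to measure would otherwise inflate the
classical covariance and mask themselves.  Two degenerate regimes are
handled explicitly: a constant gene raises a typed error naming the gene,
and n ≤ 2m falls back to the classical mean/covariance with a logged
warning (small validation cohorts meet large gene sets).  With full
support the model reduces exactly to the classical moments, which is how
the brute-force oracle tests pin the arithmetic.

The dimension of the covariance deserves a note: only the m×m gene–gene
covariance across individuals is dimensionally consistent with the MD
quadratic form and the χ²_m reference (an n×n individual–individual
covariance cannot multiply an m-vector), and it is the form the MCD can
estimate when n > 2m.  That is what this package implements, with df = m
throughout.

## Permutation machinery

Empirical p-values use the add-one rule p = (1 + #{null ≥ obs})/(n_perm+1),
so they are never zero; both one-sided tails are computed for every set.
Significance testing escalates sequentially: start at 1,000 permutations
and multiply by 10 while the Clopper–Pearson 99% interval of the exceedance
proportion still straddles the Bonferroni level α/n_sets, up to a
configurable cap — i.e. until the corrected level is achieved or rejected.
Null distributions are cached per (matrix fingerprint, m) and extended in
place, because thousands of sets share a handful of sizes; permutation j
for a given (matrix, m) is a pure function of the stage seed, so cached and
uncached runs are identical.

The two-population statistic diffSSMD = SSMD_A − SSMD_B uses distances
computed **once** on the pooled matrix with a single robust model; its null
shuffles the group labels at the fixed n₁/n₂ ratio without recomputing
distances.  Its expectation under the null is (n₁ − n₂)·E[MD²] ≈
(n₁ − n₂)·m, linear both in the group imbalance and in the set size —
properties the acceptance checks verify on simulated 326/76 cohorts.
Significance keeps the strict all-exceedance rule (observed beyond every
null value, p ≤ 1/(n_perm + 1)); it is conservative, but reproducible and
monotone.

## Twin discordance

For one gene in one twin pair with values y₁, y₂, the relative mean
difference RMD = |y₁ − y₂| / (2·(y₁+y₂)/2) is a scale-free discordance
measure; per-gene mean RMD pools all pairs of one zygosity and is
normalized by the same quantity under random re-pairings of the sample
pool (default 100 re-pairings, within zygosity), so ~1 means "no more
discordant than strangers".  RMD presumes a positive expression scale:
genes with any non-positive pair mean are dropped with a logged count
rather than clipped.  The synthetic twin model is the classical ACE-style
decomposition — additive genetic (shared fully by MZ co-twins, correlation
½ for DZ), shared environment, unique environment — with
environment-sensitive genes given an inflated unique-environment SD.  Under
this model DZ discordance exceeds MZ discordance whenever the genetic
variance is positive, and environment-sensitive genes separate from the
rest in MZ pairs; heritability and single-cell-CV comparisons reuse the
same two-sample Kolmogorov–Smirnov machinery on externally supplied
per-gene metrics (no estimation is implemented).

## eSNP effects

An eSNP's effect size |β| is the absolute OLS slope of Z-scored expression
on genotype dosage {0, 1, 2} (Z-scoring decouples β from expression level;
the sign is meaningless without an allele reference).  The genotype-scaled
effect β* = |β|·genotype is zero exactly for homozygous-major carriers, so
the fraction of zeros in a pooled (individual, gene, eSNP) collection is
the fraction of genotype-0 calls.  Outlier and non-outlier pools are
compared by a 2×2 χ² test on zero/nonzero counts and a two-sample K-S on
the nonzero values.  In the package's synthetic cohorts, aberrance is
driven by planted multivariate displacement and private variants while
eSNP genotypes are drawn independently of outlier status, so this
comparison is a negative control: the clean-rate reported by the
acceptance script is the fraction of simulated cohorts where the χ² test
correctly finds nothing.

## Private variants

A SNP is private to individual s when s is the only carrier of the
alternate allele (heterozygous, allele frequency 1/(2N), or homozygous,
1/N); missing genotypes exclude a sample from carrying but do not
disqualify privacy.  Cis windows are TSS-centred, 1 Mb total by default
(the anchor and width are configurable and logged — gene-body anchoring is
a defensible alternative), clipped at chromosome bounds, 0-based
half-open; a 1-based variant position p lies in [s, e) iff s < p ≤ e.
Chromatin-state territory per class (E, TSS, CTCF, T, PF, R, WE, UNCL) is
the segmentation intersected with the merged union of windows, so overlap
between windows is never double-counted; SNPs are deduplicated within a
class.  Density = pooled SNP count / territory in Mb.

Four control constructions give the enrichment reference: (1) outlier
individuals replaced by equally many random non-outliers; (2) windows
rebuilt 10 Mb away from the genes (sign drawn per gene per replicate, with
a chromosome-bound fallback, so the scheme yields a distribution rather
than a single translated value); (3) each aberrant gene list replaced by a
random same-size draw from the expressed-gene pool; (4) the same drawn
from S-class genes.  Outliers that share a gene set share the replacement
draw in schemes 3–4 — independent per-outlier draws would change the
territory denominator and bias neutral classes.

The enrichment p-value is a one-tailed single-case t test
(Crawford–Howell): t = (observed − mean(controls)) / (sd(controls)·
sqrt(1 + 1/n)), df = n − 1.  The sqrt(1 + 1/n) factor matters: the
observed density carries the same replicate-level sampling noise as each
control draw, and omitting the factor (testing the control mean against
the observed value as if noise-free) makes the null p anticonservative by
a factor of sqrt(n) — in simulation it flags unenriched classes at p <
0.01 in a third of runs.  With the factor, the null p is uniform and a
planted 2× enhancer rate is still detected at p < 0.001.

## The synthetic-data generator

The generator is the package's model of what population expression data
look like, and its defaults are the study conditions for every recovery
test:

* **Correlated gene-set blocks**: exchangeable correlation ρ (default 0.9
  for planted sets) from a shared factor plus residuals.
* **Hidden multivariate outliers**: planted individuals are displaced
  along a contrast orthogonal to the shared factor — the minor
  eigendirection, eigenvalue 1 − ρ — with magnitude parameterized in
  Mahalanobis units.  A displacement of δ yields per-gene z-scores of at
  most δ·sqrt(1−ρ)/sqrt(m'), so at ρ = 0.9 a δ = 12 outlier never exceeds
  |z| = 2 on any single gene: multivariately extreme, univariately
  unremarkable.  A displacement that would violate the requested z-bound
  raises an error instead of silently planting a visible outlier.
* **Sporadic per-gene aberrance**: real transcriptomes contain genes with
  occasional large single-individual expression excursions; the generator
  gives each ordinary gene a few (default 3) spiked individuals at ~6 SD.
  This is what gives random gene sets their SSMD excess: under exact
  multivariate normality MD² ~ χ²_m regardless of ρ, and no set could be
  significantly *small*.  S-class sets are clean, tightly coupled blocks
  (ρ = 0.95, no spikes) and therefore fall in the null's lower tail.
  Spiked individuals are recorded in the truth manifest: they are planted
  aberrance, and outlier-recovery tests count them.
* **Two-population structure**: per-population residual SD multipliers on
  set genes (e.g. 2× in the smaller population) generate
  population-specific aberrance for the diffSSMD tests; default cohort
  sizes mirror a 326 + 76 two-population design.
* **Genotypes**: singletons are planted per individual at a base rate per
  Mb of class territory (Poisson), with class-specific multipliers inside
  outlier individuals' aberrant-gene windows; eSNPs are HWE draws at a
  given MAF near the TSS with linear expression effects available for
  injection.  The emitted VCF/BED round-trip through the package's own
  readers, and `find_private_snps` on the re-read VCF reproduces the
  planted singleton lists.

What the generator does **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra, gene-length and GC effects, count noise,
batch/technical structure, and non-exchangeable correlation within sets.
Passing recovery tests therefore show that the statistics detect the
structure they are defined on, at realistic sizes — not that real-data
significance calls are correct at these thresholds.

## Benchmark sizes and budgets

The packaged benchmark uses one population of 160 individuals, 15 L sets
(6 hidden outliers each, δ = 12), 15 S sets and 50 null sets, all of size
10, in a 1,500-gene matrix.  Each MCD fit costs tens of milliseconds, and
Bonferroni 0.01/80 needs the shared null escalated to 10⁴ permutations, so
the full benchmark classification runs in a few minutes on one core; these
sizes were chosen so the complete recovery analysis (sensitivity ≥ 0.8 for
both classes at FDR ≤ 0.1) is an everyday check rather than a cluster job.
Power analyses default to the traditional 100 replicates × 1,000
permutations but are exercised at reduced grids in the test suite.

## Numerical choices

* Scatter inversion via Cholesky (`scipy.linalg.cho_solve`); tiny negative
  quadratic forms from roundoff are clamped to zero.
* χ² quantiles and all distribution functions from `scipy.stats`.
* The chi-square plot ordinate is squared MD (the only version for which
  the χ²_m reference is exact); the export carries rank, p, χ² quantile
  and MD².
* K-S tests use `scipy.stats.ks_2samp` (asymptotic/exact switch left on
  "auto"); 2×2 χ² uses Yates continuity correction.
* Degenerate contingency tables (a margin of zero) return p = 1 rather
  than an error: there is no testable difference.
* All randomness flows from one master seed through named
  `numpy.random.SeedSequence` spawns (stage, set name, replicate index), so
  any stage is reproducible in isolation and cache state cannot change
  results.

## Known limitations

* The MCD's finite-sample inflation makes the χ²(0.975, m) outlier cutoff
  slightly liberal (empirical false-positive rate ≈ 3–4% at n = 400,
  m = 10); a reweighted cutoff or hard calibration could tighten this.
* The strict all-exceedance diffSSMD rule cannot produce p-values below
  1/(n_perm + 1) and wastes no multiplicity control; it is kept for
  fidelity and transparency.
* Permutation nulls treat genes as exchangeable; strong global expression
  structure (e.g. unremoved batch effects) would violate this, which is
  why the PCA sample QC runs first.
* The escalation cap bounds the smallest achievable p-value; sets that hit
  the cap undecided are reported as neutral with the reached bound logged.
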