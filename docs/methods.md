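# Methods

## Scope and model

`rilmap` maps quantitative trait SNPs (QTSs) in a biparental recombinant
inbred line (RIL) population and predicts breeding values from the fitted
effects. The observation model for line *k* in environment *h* is the
saturated mixed linear model

    y_hk = mu + Σ_i a_i x_ik + Σ_{i<j} aa_ij x_ik x_jk
         + e_h + Σ_i ae_hi x_ik + Σ_{i<j} aae_hij x_ik x_jk + eps_hk

with genotype codes x ∈ {+1 (paternal homozygote), −1 (maternal
homozygote)}. Dominance is structurally absent: RILs are (near-)
homozygous, so only additive and additive-by-additive terms are
estimable. No kinship or structure correction is applied; in a biparental
RIL population relatedness is uniform by construction.

## Genotype simulation

Single seed descent is simulated forward: an F1 from two fully homozygous
inbreds is selfed `n_selfing_generations` times (default 12 → F13), one
progeny per line per generation. Crossovers follow the Haldane model
(Poisson, no interference): adjacent markers at map distance d cM
recombine per meiosis with r = (1 − e^(−2d/100))/2, independently across
intervals and meioses. Two independent gametes per selfing build the next
genotype. Expected residual heterozygosity after 12 selfings is ~0.02%
per locus; by default (`het_policy="force-homozygous"`) residual
heterozygotes are assigned to a parental class by fair coin flip,
matching a fully homozygous ±1 coding; `"code-missing"` records them as
missing instead. Missing calls can be injected uniformly at a configured
rate (default 0) to exercise the QC filters.

Two checks anchor the simulator: (a) allele frequencies converge to 0.5;
(b) adjacent-marker genotype correlation converges to the
Haldane–Waddington fixed point (1 − 2r)/(1 + 2r). A 2-million-line run
put the F13 deviation from this F∞ limit below 0.001 for
r ∈ {0.01, 0.05, 0.1, 0.25}, so at the test scale (50,000 lines) Monte
Carlo noise dominates, not generation-count bias.

What the simulator does not emulate: crossover interference, segregation
distortion, genotyping error biased by sequencing depth, residual
heterozygosity hotspots, and non-Gaussian trait distributions. Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated generative model, not robustness to every artefact of
real re-sequencing data.

### Phenotypes

Fixed genetic values come from configured `a`/`aa` effects; `e_h` is
drawn once per environment (shared by all lines in it), `ae`/`aae` once
per (environment × term), residuals per observation, all normal with
configured standard deviations. Defaults mirror the experimental design
the package targets: 138 lines, two environments × two replicates.

## Quality control

Order: missing-rate filter, then segregation filter (a MAF filter exists
but is off by default — in a balanced biparental cross MAF ≈ 0.5 is an
outcome of the design, not a screening criterion).

* Missing rate: drop SNPs with missing fraction strictly greater than
  5% ("exceeds" read literally).
* Segregation: plain Pearson chi-square (1 df, no continuity correction)
  of the two homozygote counts against 1:1, dropped when the statistic
  exceeds the α = 0.01 critical value (6.635). SNPs with zero calls are
  dropped and flagged.
* Heterozygous VCF calls default to missing rather than error — low-pass
  sequencing data plausibly contains het artefacts.

## LD analysis

r² is the squared Pearson correlation of ±1 codes over lines non-missing
at both SNPs; pairs are complete within a same-chromosome window
(default 1 Mb; an optional k-nearest-neighbour mode reproduces the
shrunken decay estimates that neighbour-limited windows produce). The
decay curve averages r² in half-open bins (default 1 kb); pairs are
pooled across chromosomes before binning. The half-decay distance is the
start of the first bin at or below half the maximum *binned* mean (the
empirical curve's maximum, not the theoretical r² = 1); if the curve
never drops that far the result is explicitly undefined (None). No
smoothing is applied by default; a moving-average window is exposed.

## SNP-set strategies

Genome-wide (GWA) uses all QC-passing SNPs; QTL-based (QBA) keeps SNPs in
BED intervals (0-based half-open); gene-based (GBA) keeps SNPs within
full gene spans from GFF3 (1-based inclusive; UTRs/introns included,
since genic membership is defined by the annotated footprint). SNP
positions are 1-based throughout. A SNP hit by several intervals/genes is
kept once with all labels recorded.

## Screening

Large SNP sets are pre-filtered by F-statistic ranking before mapping:
per SNP, the one-way F of line-mean phenotype on genotype; per pair, the
partial F of the product term given both marginals (universe defaults to
pairs among the top 2,000 marginal SNPs, configurable to exhaustive).
Screens run per environment on within-environment line means and merge
by union, so per-trait candidate totals can exceed the per-screen
`top_m` (default 1,000). Screening is a pure filter: with
`top_m = n_snps` the downstream fit is bit-identical to mapping without
screening (a tested invariant). F statistics are invariant to affine
phenotype transforms.

## Two-step mapping

Step 1 tests each SNP's additive term by F-test in a fixed-effects model
with the environment as a block, on replicate-level observations. Step 2
tests each pair's product term conditioning on the environment block, the
step-1 significant SNPs as covariates, and the pair's marginals.
The environment is fixed in the scans (speed; permutation validity
within environment) and random in the final fit, matching its designation
in the full model.

Thresholds are experiment-wise: line labels of the phenotypes are
shuffled within each environment (1,000 permutations by default, α =
0.05), the scan re-run, and F* taken as the empirical (1 − α) quantile
of the max-F distribution. For balanced designs the permutation scan
uses a sufficient-statistic shortcut (within-environment means and sums
of squares are permutation-invariant, so only per-line phenotype sums
permute), verified identical to the direct computation. Degenerate
zero-residual fits report an infinite-F sentinel; non-finite statistics
are excluded from max-F. Under null simulation the realised
experiment-wise type-I error is checked to lie in [0.03, 0.07].

### Stepwise selection

Selection units are single loci and epistasis pairs (marginal + product
block). Forward steps admit the unit with the smallest partial-F p-value,
backward steps drop units whose partial-F p exceeds the stay level.
Two design choices matter and were made deliberately:

* Default entry/stay levels are 0.05 / n_units (Bonferroni over
  candidate units) for direct API calls; the pipeline instead derives
  them from the step-1 permutation threshold, so a unit must clear the
  same experiment-wise F level to enter or stay. With nominal 0.05
  levels, ~1 spurious unit entered per run on diagnostic simulations;
  with the experiment-wise level, selections match the planted
  architecture (exact-set recovery 97% on a 30-replicate diagnostic at
  n = 138 with three strong QTSs).
* An entry guard caps the absolute correlation between an entering
  unit's columns and the current design (default 0.9). Without it, dense
  marker panels let tightly linked neighbours of a selected QTS enter as
  near-collinear pairs with inflated opposite-sign effects (observed
  total h² up to ~145% on a 0.25 cM map). The guard selects one
  representative per LD block; distinct loci in moderate LD still
  compete on partial F. Consequence: two true causal variants with
  |r| > 0.9 cannot be separated — a stated resolution limit, not a bug.

Ties on entry break by larger F, then smaller (chromosome, position);
rank-deficient additions are skipped, so of two perfectly collinear
candidates exactly one is selected.

## Gibbs estimation

The selected model is estimated by Gibbs sampling (default 20,000
iterations, first 25% burn-in, no thinning): fixed effects (mu, a, aa)
with diffuse normal priors N(0, 10⁶ · var(y)); random e, ae, aae vectors
with scaled-inverse-chi-square variance priors, ν₀ = 2 and scale s₀² set
to 1% of the initial least-squares residual variance (empirical scaling;
a var(y)-scaled prior leaves the interaction variances wide enough to
absorb additive signal in near-noise-free data). All full conditionals
are conjugate; chains start at the OLS solution; variance draws are
floored at 10⁻¹² · var(y). Point estimates are posterior means, standard
errors posterior sds, p-values a Wald-type normal approximation on
mean/sd (reported as −log10 P). Reproducible bit-for-bit given a seed.

Per-QTS heritability: h²_i (%) = 100 · a_i² · var(x_i) / V_P (pairs use
var(x_i x_j)), where V_P is the sample variance of line-by-environment
mean phenotypes — the one inferred formula in the package, chosen because
it reproduces the internal ratios of the published per-QTS tables
(effect-ratio² vs h²-ratio agree within ±0.03 across all 31 rows). The
total is the sum of the individual values; marginal variances ignore
covariance between selected loci, which is why one-per-LD-block selection
matters upstream.

## Prediction

G = Σ a_i x_i + Σ aa_ij x_i x_j; predicted phenotype mu + G (constant
across environments when no QTS-by-environment terms are selected). The
best line maximises G over observed lines (mean-imputed at selected
loci; ties keep the first line and are flagged). The superior line
searches homozygous genotypes {−1,+1}^k: closed form sign(a) for purely
additive models, exhaustive enumeration for k ≤ 20 with epistasis, else
simulated annealing (geometric temperature ladder 0.5→10⁻⁴ × effect
scale, factor 0.9, 4k flips per level, 50 restarts, greedy polish,
seeded) with incremental single-flip scoring; annealing matches
exhaustive enumeration on 50 random 12-locus epistatic models (tested).

## Problem sizes used in the test suite

Simulation-based checks run at: type-I error — 200 null datasets of
2,000 SNPs × 138 lines with 200 permutations each; parameter recovery —
100 replicates of six additive QTSs (|a| ∈ [1.8, 3.0], total h² ≈ 40%)
at n = 138 with full 20,000-iteration chains; LD oracle — 50,000 lines;
the acceptance pipeline — a 12-chromosome, ~2,000-SNP genome at 0.25 cM
marker spacing. These sizes are the package's own scaled-down testbed
choices; the statistical criteria they verify (error rates, coverage,
closed-form agreement) are size-calibrated accordingly.

## Known limitations

* Heterozygous genotypes are out of model scope (no dominance), so F1 or
  hybrid performance is not predictable from these fits.
* The stepwise collinearity guard bounds mapping resolution at |r| = 0.9
  between causal variants.
* Effect estimates carry winner's curse at n = 138 when conditioned on
  selection; the parameter-recovery guarantee applies to estimation at
  given loci, not to post-selection inference.
* Permutation thresholds assume exchangeable lines within environment;
  the fast path additionally assumes a balanced replicate structure and
  falls back to the generic path otherwise.
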