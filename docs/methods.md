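# Methods

`rohload` studies how the deleterious mutation load of a small, historically
bottlenecked population is distributed over runs of homozygosity (ROH) of
different genetic lengths, and how ROH of different lengths contribute to
inbreeding depression in first-year survival. This note documents the models,
the parameter choices and their rationale, the numerical decisions, and what
the synthetic-data tests do and do not demonstrate.

## Genetic map and haplotype age

Markers are placed on a sex-averaged linkage map by piecewise-linear
interpolation of cM positions in physical coordinates, i.e. assuming a
constant recombination rate between mapped anchors. Markers before the first
anchor of a chromosome get 0 cM; markers past the last anchor inherit its cM;
markers between anchors of identical cM collapse onto that value. cM values
are doubles; comparisons use an absolute tolerance of 1e-9 cM.

The age interpretation of segment lengths uses the classical expectation for
the genetic length of an identity-by-descent segment whose two haplotypes
coalesce `g` generations ago:

    L = 100 / (2 g)  cM.

The three ROH length classes and their approximate ages are: long (> 12.5 cM,
MRCA within ~4 generations), medium (1.56–12.5 cM, ~4–32 generations), short
(0.39–1.56 cM, ~32–128 generations). The class boundaries 1.56 and 12.5 are
assigned to the medium class so that every segment has exactly one class. The
actual length distribution around the expectation is approximately
exponential, so these are expectations, not sharp age cut-offs.

## ROH detection

Detection re-implements the windowed scanning semantics of PLINK's
`--homozyg` on genetic-map coordinates. cM positions are multiplied by 1e6 and
rounded to integers, so the standard kb-scale parameter idiom maps exactly
onto cM thresholds (390 kb ≙ 0.39 cM etc.) and all length/gap/density
arithmetic is integer-exact. Defaults: 25-SNP windows, a window is a hit with
at most 2 heterozygous and 2 missing calls; a marker is eligible when at least
5% of covering windows are hits (the scanning tool's default, exposed as a
parameter since it is not part of the printed command idiom); eligible runs
are split at inter-marker gaps above 0.25 cM; final segments need ≥ 25 SNPs,
≥ 0.39 cM, ≤ 0.1 cM per SNP average spacing, and at most 2 heterozygous calls.

Where a run contains more heterozygotes than the allowance, every maximal
sub-interval within the allowance is considered, trimmed to homozygous
endpoints, and accepted longest-first (ties to the left) without overlap.
This makes the caller deterministic and byte-reproducible, and matches an
exhaustive-enumeration oracle in the settings where the oracle's maximal
intervals are unique (zero-het fixtures). The segment span runs from the
first to the last marker of the segment; it is not extended into unobserved
territory.

Two consequences of the window semantics worth knowing: a homozygous stretch
of exactly 25 markers flanked by heterozygotes is *not* called (its markers
are covered by exactly one hit window out of up to 25, and 1/25 < 5%), and
called segments are typically trimmed by one marker at each end relative to a
planted truth segment. Tests therefore compare plants with a one-window
tolerance.

F_ROH per class is the summed class segment length divided by the total map
length (3146 cM for the Soay autosomal map); `f_total` sums all classes, and
individuals without segments have zero coefficients and a missing mean length.

## Wright–Fisher simulation

A single 100 Mb chromosome with uniform per-bp recombination and mutation
rates of 1e-8 (so 1 Mb ≙ 1 cM), discrete generations, monoecious random
mating with selfing, soft selection (fitness-proportional parent choice,
fixed offspring number). New mutations arise at Poisson(μL) per gamete; 70%
are deleterious with gamma-distributed selection coefficients (mean s ∈
{−0.01, −0.03, −0.05}, shape 0.2) and a shared dominance coefficient h ∈
{0, 0.05, 0.2}; 30% are neutral and simulated forward in time (they serve as
genotyping markers; the load statistics depend only on the deleterious set).
Fitness is multiplicative, `1+s` per homozygous and `1+h·s` per heterozygous
mutation, clamped at zero, and evaluated on the log scale because products of
thousands of factors underflow under strong rescaling. Fixed mutations are
removed from the segregating set; their load contribution is deliberately
excluded, matching a segregating-mutation load measure.

The demographic history models the Soay population: N = 1000 for 10,000
generations, an instantaneous change to 200 at island colonisation for 970
generations, a one-generation crash to 10 individuals 30 generations before
sampling, exponential recovery to 200 within 20 generations
(N(t) = round(10·20^(t/20))), then 200 for the remaining generations (11,000
total).

Positions are integer base pairs under an infinite-sites convention (a
position is never reused; collisions are re-drawn). Haplotypes are
position-sorted arrays of mutation ids with deleterious and neutral ids kept
separately, so fitness only touches the deleterious set; recombination merges
parental arrays at Poisson(rL) breakpoints (numba kernels).

### Rescaling

`rescale_config` divides population sizes (rounded, floored at 2) and epoch
durations (rounded up) by Q and multiplies μ, r and mean s by Q, preserving
N·μ, N·r and N·s. Two artifacts of Q = 10 matter for interpretation:

* about 9% of rescaled selection coefficients fall below −1 (recessive
  lethals). Because each census slot should hold a living individual, the
  simulator re-draws offspring with fitness exactly 0. At an N = 2 bottleneck
  with selfing this conditioning is what keeps runs viable;
* one rescaled generation corresponds to 10 meioses, so the youngest possible
  IBD segments have expected length 5 cM (1 Mb ≡ 1 cM reading). The long
  class (> 12.5 cM) is then the length tail of young haplotypes rather than a
  distinct age cohort, and the crash floor of 2 (10/10 rounded up to the
  minimum) makes the founder event more severe than at full scale. Both
  effects inflate contrasts against the short class; see "Replicate
  experiment" below.

### Sampling census

In the replicate experiment the rescaled history is simulated as derived, but
the final (sampled) generation is run at the study census of 200 individuals
rather than the rescaled 20. This choice was made on design grounds: the
published statistics average over 200 individuals per replicate, and a
20-individual sample segregates only ~1000 sites (~10 per cM), a density at
which the 0.25 cM gap rule fragments every candidate ROH and the caller
returns nothing. At census 200 the sample segregates ~4500 sites (~45 per
cM), comparable to the regime the detection parameters were designed for.

## Load statistics

Per individual and length class: the load per cM (sum of selection
coefficients of exposed deleterious mutations divided by the class's summed
segment length), the count per cM, and the mean population allele frequency
of the exposed mutations. "Exposed" means homozygous for the deleterious
allele within the (closed) segment interval — ROH mark IBD tracts and the
heterozygous calls tolerated inside them are treated as non-IBD contamination;
counting any carried copy is available behind a flag. Individuals without
segments of a class are excluded from that class's mean (load per cM is
undefined without ROH), not counted as zero. The mean allele frequency counts
each mutation once per individual-occurrence; population-unique weighting is
an option.

Replicate summaries average the per-individual statistics over individuals;
experiment-level contrasts are computed from the across-replicate grand means
as `100·(1 − mean_class / mean_long)`, long ROH being the baseline.

## Replicate experiment

The headline configuration is Q = 10, gamma DFE with mean s = −0.03, shape
0.2, h = 0.05, 20 replicates (~23 s each on one core), seeds derived from one
master seed via named spawning. Under these conditions the qualitative
patterns are robust: |load per cM| orders long > medium > short in ~95% of
replicate sets, and deleterious mutations found in long ROH are rarer than
those in short ROH. The medium-vs-long load contrast lands in the 23–36%
range depending on the seed (the long-class mean rests on the minority of
individuals carrying long ROH, so it is the noisiest statistic), around the
26% seen at full scale. The short-vs-long load contrast (~70–73%) and the
medium-vs-long count contrast (~25–30%) overshoot their full-scale
counterparts (56% and 10%); the rescaling artifacts above (blurred
long/medium age separation, min-2 crash floor) push both numbers up, and
closing that gap would require Q ≤ 2, an orders-of-magnitude larger
computation. The numbers are reported as computed.

## Survival model

A Bayesian binomial GLMM with logit link:

    Pr(surv_i) = logit⁻¹(β0 + 100·f_long·β1 + 100·f_medium·β2 + 100·f_short·β3
                         + sex·β4 + twin·β5 + a_birthyear + a_mother),

with Normal(0, σ²) random intercepts per birth year and mother, Normal(0, 5)
priors on fixed effects, and half-Student-t(3, 2.5) priors on the two group
SDs (the degrees/scale are this package's defaults, exposed in `ModelConfig`).
The ×100 covariate scaling makes each β a log odds ratio per 1% of genome.
The alternative parameterization replaces the three class terms with
100·f_total and the individual's mean ROH length in cM.

Inference integrates the crossed random intercepts out with a Laplace
approximation: the conditional modes solve a penalized logistic problem by
damped Newton iterations on a sparse system (two diagonal blocks plus a
year×mother coupling block, LU-factorized; warm-started between evaluations),
and the marginal adds the half log-determinant correction. The resulting
8-dimensional marginal posterior over (β, log σ_by, log σ_mo) is summarized
two ways:

* `map` — L-BFGS maximization plus a central-difference Hessian for a
  Gaussian approximation; interval endpoints are normal quantiles, and group
  SD intervals are exponentiated from the log scale. No Gelman–Rubin
  statistic exists for this backend (reported as missing).
* `mcmc` — several independent affine-invariant ensembles (emcee) initialized
  near the MAP; percentile intervals from pooled draws and Gelman–Rubin per
  parameter across ensembles (arviz), with the fit flagged non-converged at
  R̂ ≥ 1.1. `ModelConfig` expresses chains/iterations/warmup in total draws
  per chain (defaults 4 × 10,000 with 5,000 warmup) and the ensemble spreads
  them over its walkers.

With ~5000 observations the marginal posterior is very nearly Gaussian and
the two backends agree to well within Monte-Carlo error; the fast backend is
used for repeated parameter-recovery fits (~9 s per fit), and the test suite
cross-checks both against statsmodels' variational/Laplace mixed GLM on the
slope coefficients. Degenerate inputs raise informative errors:
single-level grouping factors, constant predictors (detected at a relative
variance threshold of 1e-10), non-binary outcomes, and implausibly large
fixed effects (|β| > 10, the signature of complete separation). Records with
a missing mother id are dropped with a warning counting them.

Estimates are reported as odds ratios with 95% intervals and the percent
change in odds, `100·(1 − OR)`.

## Synthetic data

The cohort generator draws the three inbreeding coefficients independently:
f_long from a zero-inflated gamma (zero probability 0.3, shape 0.8) matching
the strongly right-skewed published distribution with mean 0.013; f_medium
and f_short from truncated normals with means 0.213 and 0.107 and SDs 0.035
and 0.015. Rows whose class sum would exceed 1 (vanishingly rare) fall back
to the long-class mean. Defaults mirror the study scale: n = 4879, 39 birth
years, 29 mothers per year, twin probability 0.15 (not published; chosen as a
plausible lambing rate and configurable), sex ratio 0.5, group SDs 0.3, and
fixed effects at the published odds ratios (intercept 2.3, chosen to put mean
survival near 0.5). Distribution *shapes* are package choices; only the means
are anchored, so cohort tests validate estimator behaviour, not the shape of
the real F_ROH distributions.

The genotype-fixture generator plants homozygous segments of known span and
heterozygote contamination on a uniform 0.05 cM marker grid over a background
of 55% heterozygous, 2% missing calls. The background rate is a deliberate
stress level: at the 2-het window allowance, realistic backgrounds produce
correct-but-spurious homozygosity calls that have no planted counterpart,
while 0.55 drives the false-hit probability per window to ~1e-6 so every
called segment can be matched against the truth table. Fixture tests
therefore demonstrate caller correctness against a known truth, not
performance on realistic heterozygosity landscapes.

What the synthetic data do not emulate: linkage disequilibrium and realistic
allele-frequency spectra in the fixture genotypes, correlation between the
three F_ROH coefficients, pedigree structure beyond crossed year/mother
intercepts, year-specific mortality, and real marker ascertainment. Passing
tests show the pipeline's operations are correct and its estimators recover
known parameters under the model's own assumptions.

## Problem sizes and runtimes (single core)

Chosen so the full suite and the acceptance computation each run comfortably
in tens of minutes: 20 Soay-history replicates at Q = 10 (~9 min), neutral
calibration with N = 50 over 10 Mb × 20 replicates (~1 min), 20 + 3 GLMM fits
at n = 4879 and n = 1500 (~4 min), 100 brute-force oracle instances of ≤ 200
markers plus 50 planted fixtures (~1 min).
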