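# rohload

Tools for studying how the deleterious mutation load of a small, inbred
population is distributed across runs of homozygosity (ROH) of different
ages, and how ROH length classes contribute to inbreeding depression.
Developed around the wild Soay sheep system (a feral island population with
~4900 lambs phenotyped for first-year survival and dense SNP genotypes), but
every stage runs on synthetic data and is reusable for similar analyses.

The package implements five connected pieces:

1. **Genetic map** — linear cM interpolation of marker positions between
   linkage-map anchors, and the haplotype-age conversion `L = 100/(2g)` cM
   linking a segment's genetic length to the expected number of generations
   `g` to the most recent common ancestor of its two haplotypes.
2. **ROH caller** — PLINK-style sliding-window detection run on cM × 10⁶
   pseudo-coordinates (minimum 0.39 cM and 25 SNPs, ≤ 0.25 cM gaps, ≤ 2
   heterozygous calls), classification into short [0.39, 1.56), medium
   [1.56, 12.5] and long (> 12.5 cM) classes — expected coalescence ~128 to
   ~4 generations — and per-class inbreeding coefficients
   `F_ROH = Σ length / 3146 cM`.
3. **Wright–Fisher simulator** — forward-time diploid simulation of a 100 Mb
   chromosome under recurrent deleterious mutation (gamma DFE, partial
   dominance), uniform recombination, and the Soay demographic history
   (N 1000 → 200 at colonisation → crash to 10 → exponential recovery to
   200), with standard Q-rescaling for desk-scale runs and VCF export.
4. **Load statistics** — for each individual and ROH class: the mutation
   load per cM (Σs of homozygous deleterious mutations inside ROH / Σ cM),
   the count per cM, and the mean population frequency of those mutations;
   replicate summaries report percent contrasts against long ROH.
5. **Survival GLMM** — a Bayesian binomial mixed model of first-year
   survival on the three class-specific inbreeding coefficients (×100, so
   effects are odds ratios per 1% of genome), sex and twin status, with
   birth-year and mother random intercepts; crossed random effects are
   integrated out by a sparse Laplace approximation and the marginal
   posterior is summarized at the MAP or by ensemble MCMC.

A synthetic-data module generates truth-known genotype fixtures, linkage-map
fixtures and survival cohorts matching the study's scale and published
F_ROH means (0.013 / 0.213 / 0.107), so the whole pipeline is testable
without any data download.

## Worked example

```python
from rohload import (CohortSpec, generate_cohort, fit_survival_model,
                     run_replicate, aggregate_contrasts)

# 1. survival model on a synthetic cohort generated at the published ORs
records, truth = generate_cohort(CohortSpec(n=4879), seed=7)
fit = fit_survival_model(records, method="map")
print(fit.summary())
```

```
Binomial logit mixed model (map), n = 4879, converged = True
parameter               estimate      2.5%     97.5%      OR   rhat
intercept                  2.457     1.875     3.038              -
f_long_pct                -0.153    -0.185    -0.120   0.858      -
f_medium_pct              -0.088    -0.106    -0.070   0.916      -
f_short_pct               -0.024    -0.063     0.015   0.977      -
sex                       -0.360    -0.479    -0.240   0.698      -
twin                      -0.267    -0.434    -0.099   0.766      -
sd_birth_year              0.396     0.300     0.522              -
sd_mother_id               0.282     0.169     0.472              -
```

The cohort was generated with odds ratios 0.876 (long), 0.923 (medium) and
0.977 (short) per 1% of genome; the fit recovers them (0.858 / 0.916 / 0.977),
i.e. a 1% genomic increase in long ROH costs ~14% of the odds of surviving
the first winter in this draw, while short ROH have no detectable effect.
`fit.odds_ratio_table()` adds the percent-change column;
`fit.plot_odds_ratios()` draws the forest plot; `method="mcmc"` gives
percentile intervals and Gelman–Rubin diagnostics.

```python
# 2. one replicate of the rescaled Soay-history simulation (~30 s)
rep = run_replicate(seed=123)
print(rep["summary"][["length_class", "load_per_cm", "count_per_cm",
                      "mean_allele_frequency"]])
```

```
  length_class  load_per_cm  count_per_cm  mean_allele_frequency
0         long    -0.120600      1.006483               0.628877
1       medium    -0.078090      0.670845               0.639340
2        short    -0.008466      0.057194               0.598021
```

Long ROH carry the highest mutation load per cM; short ROH — old haplotypes
that purifying selection has had ~32–128 generations to clean — carry an
order of magnitude less load per cM in this draw. Averaging
`run_experiment(n_replicates=20, seed=1)` with `aggregate_contrasts` gives
the across-replicate patterns: the load ordering long > medium > short holds
in ~95% of replicates, deleterious alleles exposed in long ROH are rarer on
average than those in short ROH, and the load per cM is ~25–35% lower in
medium and ~70–73% lower in short ROH than in long ROH under the rescaled
headline scenario (the medium contrast is the noisiest of the three: the
long-class baseline rests on the few individuals carrying long ROH).

## Command line

Each stage is also a `rohload` subcommand operating on files:

```bash
rohload interpolate-map --map map.tsv --bim data.bim --out markers_cm.tsv
rohload call-roh --vcf sample.vcf --out roh.tsv
rohload froh --roh roh.tsv --map-length 3146 --out froh.tsv
rohload simulate --mean-s -0.03 --h 0.05 --replicates 5 --rescale 10 \
    --seed 42 --outdir sims/
rohload load-stats --vcf sims/rep0.vcf --mutations sims/rep0_mutations.tsv \
    --roh roh.tsv --out stats/
rohload fit-survival --data cohort.tsv --out fit.json
rohload make-synth cohort --seed 1 --out synth/
```

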