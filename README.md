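# msatpop

Population-genetic analysis of fragmented populations from diploid
microsatellite genotypes — built for studies of sessile coastal organisms
(e.g. habitat-forming seaweeds) sampled across a site → sea → basin
hierarchy, where the questions are: how much diversity is left in each
remnant population, are heterozygote deficits technical or demographic,
how structured are the populations, and how far does a propagule disperse
per generation?

The package covers the full inference chain:

* **I/O** — Genepop text files and a long-format CSV; site metadata with
  WGS84 coordinates and the site/sea/basin nesting.
* **Data quality** — clone screening via the probability of identity (PI);
  null-allele frequencies by EM under the blanks-as-null-homozygotes model;
  one-sided exact binomial test of observed blanks; short-allele-dominance
  (Spearman of allele size against per-allele F_IS/F_IT) and stuttering
  screens; G-based linkage-disequilibrium tests; Benjamini–Yekutieli FDR.
* **Diversity** — alleles per locus, rarefied allelic richness A_r,
  Nei gene diversity H_S (small-sample corrected), multilocus
  heterozygosity, randomization-based group comparisons.
* **Structure** — Weir–Cockerham *f* (F_IS), *θ* (F_ST) and *F* (F_IT) as
  ratios of summed variance components; jackknife (over loci and over
  subsamples) and bootstrap-over-loci uncertainty; permutation tests;
  pairwise θ with G-based significance; ENA-corrected F_ST (null alleles
  excluded); Cavalli-Sforza & Edwards chord distances; hierarchical
  F-statistics by nested-ANOVA variance components; the De Meeûs-style
  determination key separating null alleles from Wahlund/demographic
  deficits; Evanno ΔK summaries of external clustering runs.
* **Inbreeding** — identity disequilibrium g2 with permutation
  significance and a maximum-likelihood selfing rate with a 1-d.f.
  deviance test.
* **Dispersal** — LD-based effective population size (Burrows composite
  disequilibrium with the Waples bias correction), WGS84 Vincenty
  geodesics or user-supplied coastline distances, isolation-by-distance
  regression with Mantel significance, and the Rousset chain
  Nb = 1/b, N_e m = 1/(2πb), δ from the effective density D_e.
* **Synthetic data** — a nested Dirichlet F-model (direct control of
  θ targets, inbreeding, geometric-depth selfing, null alleles, clones)
  and a forward Wright–Fisher stepping-stone simulator with stepwise
  mutation, so every estimator has a recovery test with known truth.

## Worked example

```python
from msatpop import (SimulationConfig, simulate_hierarchical_fmodel,
                     resampling_cis, dispersal_chain)

cfg = SimulationConfig(seed=1)           # 15 sites, 3 seas, 12 loci
table, hierarchy, truth = simulate_hierarchical_fmodel(cfg)
est = resampling_cis(table, n_boot=1000, seed=1, n_perm=200)
print(f"f = {est.f:.3f}, theta = {est.theta:.3f}, "
      f"95% CI theta = [{est.ci_theta[0]:.3f}, {est.ci_theta[1]:.3f}]")

chain = dispersal_chain(0.0238, De_range=(0.014, 0.140))
print(f"Nb = {chain.nb:.0f}, Nem = {chain.nem:.2f}, "
      f"delta = {chain.delta_m[0]:.0f}-{chain.delta_m[1]:.0f} m")
```

Output:

```
f = 0.057, theta = 0.319, 95% CI theta = [0.281, 0.353]
Nb = 42, Nem = 6.69, delta = 129-409 m
```

The first line is the multilocus heterozygote deficit and differentiation
of the simulated 15-site survey (the generator's defaults put sea-level
differentiation near 0.3, so the estimate should — and does — land there).
The second line translates an isolation-by-distance slope of
b = 0.0238 into a neighborhood of 42 individuals, 6.69 immigrants per
generation, and a per-generation dispersal scale of roughly 130–410 m
across the plausible effective-density range — restricted dispersal at
the scale of hundreds of metres.

A full pipeline run (clone screen → QC → diversity → structure →
inbreeding → Ne/IBD/dispersal) is driven by a YAML config:

```bash
msatpop run --config analysis.yaml
msatpop simulate --seed 1 --out-prefix demo
msatpop dispersal --slope 0.0238 --de 0.014 0.14
msatpop evanno --table structure_lnp.csv
```

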