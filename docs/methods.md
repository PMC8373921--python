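# Methods

This note documents the statistical models implemented in `msatpop`, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Genotype model and conventions

Genotypes are unordered diploid pairs of positive integer allele codes
(fragment sizes in bp or repeat indices; a per-locus motif length converts
sizes into repeat distances where a test needs them). Missing calls are
the all-zero code, matching the Genepop convention. Pairs are stored
sorted so no phase is ever implied. Allele codes may equally be repeat
numbers; nothing downstream assumes a particular coding beyond the motif
length used by the SAD and stuttering screens.

## F-statistics

`wc_fstats` implements the Weir–Cockerham (1984) variance-component
estimators. Per locus and allele the components a (among subsamples),
b (among individuals within subsamples) and c (within individuals) are
computed from per-subsample sample sizes, allele frequencies and
allele-specific heterozygote proportions; multilocus estimates are ratios
of components summed over alleles and loci — never means of per-locus
ratios — which reproduces the weighting of the classical Fstat software.
Estimates can be negative and are reported as-is; the identity
(1−f)(1−θ) = (1−F) holds algebraically for the summed components and is
asserted in tests to 1e-12.

Two finite-sample facts worth knowing:

* identical duplicated subsamples do **not** give θ̂ = 0 — the s² term
  vanishes but the unbiased-correction term −(p(1−p)−h/4)/(n−1) remains,
  leaving a small negative O(1/n) estimate. This is a property of the
  estimator, not a bug.
* monomorphic loci contribute zero components and drop out of the ratios.

Uncertainty: per-locus jackknife over subsamples, multilocus jackknife
over loci (the `StrdErrFIS`/`StrdErrFST` of the determination key), and a
percentile bootstrap over loci (default 5000 replicates) for 95% CIs.
Percentile intervals were chosen over BCa for transparency; the bootstrap
resamples loci because loci are the exchangeable units for multilocus
F-statistics. Permutation tests follow the Fstat conventions: θ permutes
individuals among subsamples, f permutes allele copies among individuals
within subsamples (one-sided for deficit).

`hierarchical_fstats` estimates nested variance components
(basin / sea / site / individual / gene copy) by solving the
expected-mean-square equations of the unbalanced nested ANOVA (Searle
coefficients) on allele-indicator variables, summed over alleles and
loci. With a degenerate hierarchy the site/sea contrast reproduces the
Weir–Cockerham θ and the individual/site contrast reproduces f to
numerical precision — the 1984 estimator is exactly this ANOVA.

## Null alleles

The null-allele model is Hardy–Weinberg with one non-amplifying allele:
visible/null heterozygotes appear as homozygotes, null homozygotes as
blanks. `em_null_freq` maximizes this likelihood by EM per site × locus.
Because EM only creeps towards the r = 0 boundary, a boundary shortcut
returns r = 0 exactly when there are no blanks and no homozygote excess
(where the score at the boundary is non-positive). `estimate_null_
brookfield2` exposes the same ML estimate; its closed form is not
restated in the sources available, so the estimate is verified against an
independent grid-search maximizer of the same likelihood in the tests.

The one-sided exact binomial blank test asks whether the observed number
of blanks is at least what r̂² predicts: a small p means too few blanks
for nulls to explain the heterozygote deficit.

ENA-corrected F_ST recomputes the Weir–Cockerham components per visible
allele with EM-corrected frequencies (which live on the full simplex and
sum to 1−r̂) and heterozygote proportions completed for the miscalled
visible/null heterozygotes, h = h_obs (1−r̂²) + 2 p̂ r̂; the null allele
itself is excluded from the summation. With r̂ = 0 every corrected
quantity equals its observed counterpart, so the correction is exactly a
no-op on clean data.

Chord distances use the (2/π)√(2(1−Σ√(p q))) convention, bounded by
(2√2)/π; the INA variant includes the EM-estimated null as an additional
allele.

## Quality screens and the determination key

Short-allele dominance: per-allele F_IS (and F_IT) by collapsing the
locus to focal-vs-rest and applying the Weir–Cockerham estimator, then a
one-sided (ρ < 0) Spearman correlation against allele size.

Stuttering: stuttering converts one-repeat-apart heterozygotes into
short-allele homozygotes. The test conditions on the observed
heterozygotes — among them, is the one-step fraction below its share of
the expected heterozygosity? — so that processes depleting *all*
heterozygotes alike (nulls, Wahlund pooling, inbreeding) do not trigger
it. A mid-p exact binomial softens the discreteness of small counts.

The determination key combines: the permutation significance of the
multilocus deficit; the one-sided (ρ > 0) Spearman correlation of
per-locus F_IS with missing-data counts; the ratio
StrdErrFIS / StrdErrFST; and the Pearson correlation of per-locus F_IS
with F_ST. Flags:

* *null-alleles-likely*: significant deficit, significant missing-data
  correlation, and StrdErrFIS < StrdErrFST (locus-specific technical
  effects leave F_IS comparatively stable only when nulls are weak, which
  is exactly the regime where they persist undetected).
* *wahlund-or-demographic*: significant deficit, no missing-data
  correlation, non-negative F_IS–F_ST correlation, and standard errors of
  comparable magnitude (ratio within [0.5, 2]).
* *sad* / *stuttering*: any locus significant after Benjamini–Yekutieli
  control across loci.

All thresholds are arguments with the defaults above.

## Identity disequilibrium and selfing

g2 is the missing-data-robust two-locus heterozygosity-correlation
estimator: the ratio of the mean within-individual double-heterozygosity
over locus pairs to the cross-individual (i ≠ j) expectation, minus one.
It depends only on heterozygosity indicators, hence is invariant to
allele relabeling and robust to null alleles. Significance permutes each
locus's heterozygosity column independently; the SD is a bootstrap over
individuals (200 replicates, labeled as such — the reference software's
SD construction is not published).

The selfing likelihood mixes over the number t of consecutive selfing
generations, P(t) = (1−s)sᵗ truncated at t = 20 (residual mass < s²¹,
negligible for s ≤ 0.9): given t, locus ℓ is heterozygous with
probability h_ℓ/2ᵗ, loci independent given t, individuals contributing
only their typed loci. The outcrossed heterozygosities h_ℓ are profiled
by joint L-BFGS-B optimization (three starts in s); the constrained s = 0
fit has the closed-form solution h_ℓ = observed heterozygosity, and the
unconstrained fit is floored at the constrained one so the deviance
Δdev = 2(lnL₁ − lnL₀) is non-negative by construction, tested against
χ²₁. The generator implements the same geometric-depth model, so
recovery tests are tests of the estimator, not of model mismatch.

## Effective size and dispersal

LD-Ne: Burrows composite disequilibrium Δ̂ (with the n/(n−1) factor) for
every allele pair across every locus pair, r̂² = Δ̂²/(p_A q_A p_B q_B),
averaged with sample-size weights after screening alleles below P_crit
(default 0.05, exposed in config). The random-mating sampling expectation
(1/S + 3.19/S² for S ≥ 30, the small-S variant otherwise) is subtracted
and the corrected mean inverted by the standard quadratic; a corrected
mean at or below zero reports an infinite estimate. The CI propagates a
jackknife-over-locus-pairs SE through the monotone inversion.

Geodesics are Vincenty's inverse iteration on WGS84 (cross-checked in
tests against values frozen from an independent geodesic implementation),
with a spherical fallback for non-convergent near-antipodal pairs.
Coastline-path matrices are accepted as validated user input; for a
circular basin the caller keeps the shorter of the two directions.

IBD fits genetic distance (chord by default; pairwise θ or θ/(1−θ) are
available — bounded distances saturate under near-complete isolation, so
the linearized θ is preferable when differentiation is extreme) on
ln(km) by OLS over site pairs, with one-sided Mantel permutation of site
labels. The dispersal chain implements Nb = 1/b and N_e m = 1/(2πb)
exactly, and the dispersal proxy as δ = 2√(4π D_e b) (km, reported in
metres). That literal reading of the published expression reproduces the
printed worked values (129–408 m at D_e = 0.014–0.140, b = 0.0238;
186 m at the low end of the derived Adriatic density range), whereas the
dimensional reading 2√(1/(4π D_e b)) does not; both variants are
exposed, the literal one is the default, and the discrepancy is
deliberately left visible here.

## Synthetic data: what it does and does not emulate

The hierarchical generator draws sea frequencies from a Dirichlet centred
on ancestral frequencies with concentration (1−θ)/θ, and site frequencies
likewise within seas — a pure F-model giving direct control of the
differentiation targets. Defaults emulate a fragmented coastal survey:
3 seas (the last in its own basin), 5 sites each, 25 diploids per site,
12 loci with ~12 alleles, sea-level θ = 0.30, within-sea θ = 0.10, mild
inbreeding (0.05), ~3% missing calls. Per-locus θ targets are accepted
because real microsatellite panels have locus-specific effective drift
(mutation-rate variation); that heterogeneity is what makes the
F_IS–F_ST correlation informative in the determination key.

Null alleles come in two flavours: the corruption layer replaces gene
copies iid at rate r (blank rate exactly r², the closed form used in
tests), while the generator can instead make the null a *segregating*
allele that drifts through the hierarchy — the model the ENA correction
assumes, and the mode used for its recovery test. SAD severity is
proportional to the within-pair size difference over the locus size
range (the simplest monotone form); stuttering converts one-step
heterozygotes at a flat rate.

The stepping-stone simulator is a forward Wright–Fisher lattice with
nearest-neighbour migration, free recombination between loci (essential:
without it background LD swamps any LD-based Ne signal) and ±1 stepwise
mutation, demes spaced evenly so geographic distance is deme separation.

Not emulated: real allele-size distributions and homoplasy, linked loci,
overlapping generations, spatially continuous habitat, genotyping-error
processes beyond the three modelled artifact classes, and temporal
sampling. Passing recovery tests therefore shows the estimators are
correct under their own assumptions at field-study scale — not that any
particular field dataset satisfies those assumptions.

## Problem sizes and numerical choices

Simulation-based tests run at the sizes stated in their docstrings
(e.g. 10 sites × 50 diploids × 20 loci × 20 seeds for θ recovery;
200 replicates for the g2 size/power check; 10 seeds for selfing, Ne and
IBD recovery) — the scales at which the corresponding field analyses
operate. Monte-Carlo p-values use (r+1)/(n+1) smoothing and are therefore
never 0 and slightly conservative under ties, which is asserted (as level
control, not strict uniformity) in the calibration tests. EM tolerance is
1e-9 on the parameter step with a 2000-iteration cap; non-convergence
returns the last iterate. All randomness flows through
`numpy.random.default_rng` seeds carried in configs, making every output
bit-reproducible.
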