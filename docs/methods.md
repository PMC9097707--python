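# Methods

This note documents the statistical model behind `tgmeth`, the synthetic
data generator's assumptions, the numerical choices, and what the packaged
tests do and do not demonstrate about real data.

## Study design being modelled

A clonal (single-genotype) exposure experiment: mothers (F0) are exposed to
a stressor until their first brood, and descendants are reared under control
conditions to generation F4. Whole-genome bisulfite sequencing of individual
animals at F1, F2 and F4 gives per-CpG counts of methylated and total reads.
Each stressor is run inside one of two simultaneous experiments (T1 or T2)
and is always evaluated against the control line of its own experiment: the
zinc treatment against T2 controls, microcystin, high temperature and
5-azacytidine against T1 controls. The canonical comparison is "3 vs 9":
each generation's three exposed replicates are tested against the nine
pooled control samples (three per generation), which controls for
generational epigenetic drift by using a single, stable reference pool.

## Differential methylation test

**Filters** (in order, all computed over the case + control samples of one
comparison): (1) keep CpGs with ≥ 5 total reads in *every* sample;
(2) median-coverage normalisation — sample i's counts are scaled by
(median of per-sample medians)/median_i, rounded half-up, methylated capped
at total; (3) keep CpGs whose percent-methylation SD across the comparison's
samples is ≥ 0.5 points (inclusive). Re-running the chain leaves the
surviving site set unchanged; re-normalising integer counts can move
individual cells by a read of rounding.

**Model.** Counts k ~ beta-binomial with proportion p and overdispersion
φ ∈ [0, 1): Var(k) = n·p(1−p)·(1+(n−1)φ).

**Dispersion estimation.** Per site, a method-of-moments estimate that
accounts for the group proportion being estimated from the same counts:
with residual sum S = Σᵢ(kᵢ−nᵢp̂)² around the pooled p̂ = K/N,

    E[S] = p̂q̂ (A0 + A1 φ),   A0 = N − Σnᵢ²/N,
    A1 = Σ nᵢ(nᵢ−1)(1 − 2nᵢ/N) + (Σnᵢ²/N²)·Σ nᵢ(nᵢ−1)

pooled over case and control groups and solved for φ, clamped to
[1e−6, 0.99]. For equal n this reduces to the classical
S = p̂q̂·n(m−1)(1+(n−1)φ). Without the A0/A1 correction the estimator is
biased low by roughly the factor (m−1)/m per group — material at m = 3.

**Shrinkage.** φ*_s = exp(w_s·log φ_s + (1−w_s)·μ0) with
w_s = d_s/(d_s+d0), d_s the residual degrees of freedom (samples with
coverage, minus one, summed over groups) and prior strength d0 = 20. The
prior location μ0 is the median of raw log-φ over *dispersion-informative*
sites — those with at least five methylated and five unmethylated reads
pooled across the comparison. In a genome where ~99.5% of CpGs are
essentially unmethylated, the raw moment estimate at sparse sites is
clamp-censored noise; fitting the prior over all sites would collapse it to
the lower clamp. The informative-site prior also makes the label-permutation
null self-calibrating: under a permuted design, planted sites acquire
inflated within-group dispersions, the fitted prior rises, and the permuted
tests lose the spurious significance that a near-zero prior would let
through. When fewer than 50 informative sites exist the prior falls back to
log(0.01) with a warning.

**Wald test.** Group proportions are pooled over replicates' counts;
Var(p̂_g) = Σᵢ nᵢ p̂_g(1−p̂_g)(1+(nᵢ−1)φ*)/(Σᵢnᵢ)²;
z = (p̂₁−p̂₀)/√(Var₁+Var₀), two-sided normal p-value, no continuity
correction. Sites where both groups are degenerate (variance 0) get p = 1 so
downstream set algebra stays total; sites with zero coverage in a group are
skipped and counted. At φ* = 0 the statistic is exactly the two-proportion z
on pooled counts (unpooled variance across groups, matching the stated Var
formula).

*Calibration.* The plug-in normal Wald test is well calibrated in its
asymptotic regime (binomial null at ~100× pooled coverage: realised α within
binomial tolerance of nominal at 0.01 and 0.05). At the study's design
coverage it is modestly liberal at well-covered methylated sites (realised
~0.06–0.09 at nominal 0.05 for a 3-vs-9 split, the small-sample price of a
normal reference) and conservative at sparse sites (count discreteness);
pooled over a realistic tested set the realised rate is ~0.04. What matters
downstream — BH false-discovery control of the calls — holds with margin in
the planted-truth simulations (realised FDP well under 5%).

**Logistic confirmation.** With a single binary group covariate the binomial
GLM's MLE is the pair of group pooled proportions, so the likelihood-ratio
test is computed in closed form from two-binomial likelihoods (χ²₁
reference); proportions of exactly 0 or 1 are handled exactly, so no ridge
penalty is needed. Wald and LRT p-values are rank-concordant (ρ ≥ 0.9) on
simulated data.

**Multiple testing.** Step-up BH with monotonicity enforcement, applied
within each generation × treatment test, never pooled across tests. DMPs are
sites with q ≤ 0.05; direction is the sign of the methylation difference.

## Transgenerational calling

Primary definition: significant in F1, F2 and F4 (exact triple
intersection; no minimum effect size). Sign consistency is *reported*, not
enforced — the generator never flips a planted direction, and the packaged
checks require 100% consistency on recovered truth. Persistence fractions
are reported relative to F1 to one decimal. The alternative two-stage
strategy (3-vs-3 F1 screen at 20% FDR; 3-vs-3 confirmation in F2 and F4 at
unadjusted p ≤ 0.05 with matching sign) uses the Wald test by default,
configurable.

## Permutation machinery

*Label permutation:* the 18 samples of a comparison are uniformly
reassigned to the six (role × generation) cells, preserving the 3-per-cell
design shape so every permuted analysis is well defined; the full
per-generation 3-vs-9 analysis and intersection is rerun per permutation
(dispersion re-estimated each time; the coverage/SD filters depend only on
the sample set and are computed once). *Overlap resampling:* null sets are
uniform same-size draws without replacement from the tested-CpG universe;
the statistic is the k-way intersection size; p = (1+#{null ≥ obs})/(1+B)
(add-one, never exactly zero). Positional clustering of the null sets is
deliberately not modelled.

## Annotation

Coordinates are 1-based inclusive throughout (coverage-file and GFF3
convention). "Gene body" means strict containment; a gene-body site is
exonic if inside any exon of its gene, else intronic, and the three classes
partition every site. Nearest-gene ties break by distance, then leftmost
gene start, then lexicographic gene id. GO enrichment is a per-term
one-sided Fisher exact test (classic algorithm — no ontology-hierarchy
weighting) with BH across terms; the default background is the genes
carrying at least one tested CpG.

## Fitness

r solves brood1·e^(−r·age1) + brood2·e^(−r·age2) = 1 with survivorship
taken as 1 (only individuals surviving to record broods enter the table);
the left side is strictly decreasing so the root is unique. Scalar solving
uses Brent's method on [−5, 5] day⁻¹ (tolerance 1e−8) with automatic
bracket widening; bulk solving uses a damped Newton iteration verified
against the bracketed solver to ~1e−8. Individuals with no offspring get an
undefined-fitness marker, are counted, and are excluded from means.

Treatment effects: within each experiment, r is centred on its clone-line
mean (plus the grand mean) to absorb clone random effects; the effect is the
centred mean difference against the control cell of the same generation and
experiment. Intervals are percentile bootstrap (default 4000 replicates),
resampling individuals within every cell and re-estimating the clone
centring per replicate so centring uncertainty propagates. Empirical
coverage of the 95% interval is ~0.91 against each simulation's conditional
true effect at the default 30 individuals per cell. This
centring-plus-bootstrap estimator deliberately replaces a fully Bayesian
nested multilevel model: the quantities reported (cell effect vs control
with a 95% interval) are reproducible by the simpler estimator, and exact
posterior replication is out of scope.

## Synthetic data generator

The generator's defaults are the packaged study conditions; every stage
draws from an independently derived child stream of one master seed
(numpy PCG64 via `SeedSequence(master_seed, spawn_key=(stage, extra))`), so
stages are independently reproducible and outputs are byte-stable across
runs.

- **Genome/annotation:** jittered-grid CpGs (default 50,000 at ~100 bp
  spacing over 4 chromosomes); non-overlapping genes covering ~60% of the
  genome, 4 exons per gene covering ~70% of each gene; a synthetic GO
  vocabulary with 1–10 terms per gene.
- **Site methylation:** a two-component mixture — most sites near zero
  (Beta(0.5, 500)) and a methylated component at Beta(13.5, 1.5) (mean 0.9;
  invertebrate gene-body CpGs are heavily methylated), placed with odds
  multipliers of 12 for gene bodies and a further 3 for exons. The
  methylated fraction default (0.00713) is calibrated so that control
  samples call ~0.50% of CpGs methylated under the packaged call rule
  (total ≥ 1 and fraction ≥ 0.5).
- **Coverage:** per-site mappability factor times per-library factor
  (uniform 0.95–1.05), Poisson counts. The mappability factor is a
  two-component gamma mixture with mean 1: 15% "well-mappable" sites at 5×
  the genome mean (shape 8) and a poorly-mappable remainder (shape 1). A
  unimodal i.i.d. coverage law at mean 5.3× would leave essentially no site
  with ≥ 5 reads in all 18 samples of a comparison, while real studies at
  this depth retain a third of sites under that filter — a bimodal
  mappability structure reconciles the 5.3× mean with a usable tested set
  (here ~9% of CpGs after all filters, at ~15–26× among survivors).
- **Replication noise:** beta-binomial with φ = 0.02, reflecting the low
  biological variability of isogenic clone lines under controlled
  conditions.
- **Planted DMPs:** default 200 per natural stressor, ±40 points (hyper
  half from unmethylated sites, hypo half from methylated-component sites —
  one cannot hypomethylate a ~0% site; at desk scale the generator converts
  extra sites into the methylated component when the pool is too small,
  which is why fully planted runs call ~1% of control CpGs methylated
  rather than 0.5% — in a genome-scale run the planted fraction is
  negligible). Persistence classes are i.i.d. per site: transgenerational
  with probability 0.5, otherwise F1-only/F1+F2/F1+F4 at 0.6/0.2/0.2. New
  F2-only or F4-only effects are never planted. The acceptance studies use
  30-point effects as their own stated condition.
- **Demethylating drug:** modelled as multiplicative global scaling of site
  means (×0.1 in F1, ×0.9 in F2/F4), not site-specific effects.
- **Life history:** per individual, age at first/second brood (normal around
  8 and +3 days) and Poisson brood sizes (means 12 and 16), a lognormal
  clone-line brood multiplier (SD 0.05), and a stressor brood-size
  multiplier of 0.80/0.85/0.95/1.0/1.0 across F0–F4 — a negative fitness
  effect in exposed generations that recovers under control conditions.

**What the generator does not emulate** (hence what passing tests cannot
show about real data): sequence context and bisulfite conversion error;
non-CpG methylation; strand structure; within-gene clustering of planted
DMPs (planted sites are placed independently, so clustering summaries are
exercised on constructed cases, not on generator output); correlated
methylation between neighbouring CpGs; batch or library-preparation
artefacts beyond a scalar depth factor; genetic variation (the modelled
study is single-clone by design).

## Problem sizes and runtimes

Acceptance-level studies run at 50,000 CpGs (FDR study: 20 replicates with
500 planted DMPs; overlap study: 200 planted transgenerational DMPs, 1000
resamples) and 20,000 CpGs for the 100-permutation label null; the bootstrap
coverage study uses 40 replicate cohorts against conditional truths from
3000-individuals-per-cell simulations. These scales keep the full test suite
in the minutes range on a single CPU while leaving every statistical check
at its stated tolerance.

## Known limitations

- The Wald test's pointwise calibration at 3 replicates is approximate (see
  above); inference rests on BH control of the calls, which is verified.
- The tested-CpG universe at 5.3× mean coverage is a mappability-selected
  ~9% of the genome; recall figures are reported over planted sites that
  survive the filters, since unfiltered sites are untestable by design.
- GO enrichment ignores the ontology DAG; terms are treated as flat sets.
- The overlap null ignores genomic position; if real DMPs cluster within
  mappable regions, the uniform null is anti-conservative to that extent
  (the label-permutation null, which preserves all positional structure, is
  the stronger check and is also packaged).
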