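# Methods

`ecoassembly` implements the community-ecology computations used to dissect
an urban soil/lichen microbiome survey: diversity and turnover statistics,
phylogenetic and taxonomic null models that partition community assembly
into five ecological processes, compositionality-aware co-occurrence
networks, and a gradient-responsive-taxa analysis.  Every stage can be
exercised on synthetic metacommunities with known ground truth; this note
records the models, the defaults, and the reasoning behind the open design
choices.

## Assembly null models

**betaMNTD.** For samples *i*, *j* the beta mean nearest taxon distance is

    betaMNTD(i,j) = 1/2 [ sum_{k in i} f_ik min_{l in j} d(k,l)
                        + sum_{l in j} f_jl min_{k in i} d(l,k) ]

with *f* the within-sample relative abundances (abundance-weighted, the
default) or 1/S (unweighted) and *d* the patristic distance.  Minima run
over the taxa present in the other sample, so a shared taxon contributes 0.

**betaNTI.** The null shuffles the taxon → tip assignment, keeping tree
shape and count table fixed; betaNTI is the z-score of the observed
betaMNTD against `n_null` shuffles (default 999, the framework convention;
tests and the acceptance studies use 199–299 to stay at desk scale, which
only widens the z-score's Monte-Carlo noise, ~1/sqrt(2 n_null)).  The
shuffle spans **all tips of the supplied tree** by default
(`shuffle_all_tips`), not only observed taxa: the regional tree defines the
taxon pool the null draws from, and restricting it narrows the null.  Pairs
whose null distribution has zero spread — e.g. two samples with identical
taxon support, or a star phylogeny — have no defined z-score; they are
returned as NaN, excluded from profile fractions, and counted in
`n_undefined` rather than imputed.  Zero spread is detected relative to the
betaMNTD scale (`sd <= 1e-8 (|mean| + 1)`) because the variance of
numerically identical null values is cancellation noise of order 1e-9.

**RC_bray.** For each pair, `n_null` pairs of null communities are
assembled, each preserving its sample's observed richness S and total N:
presence of S taxa is drawn without replacement with probability
proportional to occupancy (implemented by Gumbel top-k, which is exact),
one individual is placed on each, and the remaining N − S individuals are
allocated multinomially with probability proportional to mean relative
abundance.  RC is the rank of the observed Bray-Curtis within the null
Bray-Curtis values, ties counted half, rescaled to [−1, 1].  Occupancy and
mean relative abundance default to estimates from the analysed table;
`reference=` supplies them from an external (regional-pool) table, which is
also how the self-calibration study removes estimation circularity.  A
presence/absence variant (`presence_only`) is available.

**Classification.** Strict inequalities, boundaries falling to the
stochastic/undominated side: betaNTI < −2 homogeneous selection; > +2
heterogeneous selection; otherwise RC > 0.95 dispersal limitation,
RC < −0.95 homogenizing dispersal, else undominated.  Profile fractions are
computed over classified pairs only; grouping is within-group pairs by
default, with `involving` (all pairs touching the group) and `all` modes,
since published per-zone fractions do not state which pairing they used.

## Synthetic metacommunities

The generator's defaults define the study conditions for every validation:
15 samples (3 groups × 5), a regional pool of 800 taxa on a Yule tree
rescaled to unit root height, pool abundances log-normal(0, 1), and 1000
reads per sample.

Selection regimes filter the pool through a Gaussian niche
`exp(−(trait − e)² / 2 sigma_w²)` on a trait evolved by Brownian motion
(rate 1.0 on the unit-height tree, so tip traits have sd ≈ 1) — betaNTI's
detection premise is exactly this phylogenetic niche conservatism.
Environments sit at quantiles of the realized trait distribution (0.9 for
the shared environment of homogeneous selection; 0.1/0.5/0.9 across groups
for heterogeneous selection): a fixed trait value can fall in an unpopulated
region of trait space on a particular simulated tree, whereas a quantile is
always populated.  Each sample additionally jitters the pool by log-normal
noise (sd 1.0, `pool_jitter`) representing local environmental variation;
without it replicate samples share essentially identical taxon sets, and a
pair with identical support carries no betaNTI information (every nearest
taxon is the taxon itself under any tip shuffle).  The niche breadth
default is sigma_w = 0.15: a pilot power study showed that wider filters
(0.3) admit so many taxa that communities overlap almost completely and the
selection signal collapses, while 0.15 with the 800-taxon pool yields
communities of ~50–80 taxa occupying a small clade neighbourhood — the
regime is then recovered as modal by the inference across seeds.  The same
pilot fixed the pool size: with 100–200 taxa the communities span half the
tree and the tip-shuffle null has almost no room to differ from the
observation.

Dispersal limitation partitions the pool into `n_regions` random disjoint
subsets (traits ignored), assigns samples to regions round-robin, and
applies one multinomial drift resampling.  Homogenizing dispersal draws
every sample multinomially from the one fixed pool composition.  The
neutral regime is a one-step immigration–drift process (local multinomial
draw, then resampling from `(1 − m) local + m pool`, m = 0.1): one step
suffices to produce |betaNTI| < 2 signatures at a fraction of the cost of
generational dynamics.

Compositional ground truth for SparCC is multivariate log-normal basis
abundances with a specified correlation matrix, closed to fractions and
multinomially sampled — the data-generating model SparCC itself assumes.

Gradient-responsive taxa: background taxa have log-normal baselines
(log-mean log 20, sd 1), planted taxa a common baseline of 30 counts,
multiplied by the fold-change `effect` in the zones of their pattern
(low-only / medium+high / high-only, cycling).  The background carries most
of the community mass deliberately: boosting taxa in one zone otherwise
depresses every other taxon's *relative* abundance there (compositional
coupling), which distorts the planted patterns the Tukey decision table is
asked to recover.

What the generators do **not** emulate: sequencing error and chimeras,
taxonomy misassignment, variable library sizes within a study arm, spatial
autocorrelation among replicates, and real phylogenetic signal strength.
Passing tests therefore show the inference machinery is correct and
calibrated under its own assumptions, not that those assumptions hold in
any particular field dataset.

## Diversity statistics

Rarefaction subsamples without replacement (multivariate hypergeometric) to
exactly the requested depth, dropping and reporting undersized samples.
PCoA is classical scaling; negative eigenvalues (Bray-Curtis is a
semimetric) are reported but uncorrected, carry no coordinates, and are
excluded from `proportion_explained`.  PERMANOVA is Anderson's pseudo-F
with label permutation and the (1 + exceedances)/(1 + N) p-value estimator,
so p is never exactly 0; R² = SS_among/SS_total.  The implementation is
cross-checked against scikit-bio's in the test suite.  Within-group
turnover is, by default, the multiset of within-group pairwise Bray-Curtis
values compared by one-way ANOVA + Tukey HSD; a betadisper-style
distance-to-centroid variant (computed in the positive-axis PCoA space) is
available because published "turnover" comparisons are frequently either.
Procrustes/protest uses the symmetric form: both configurations centered
and scaled to unit sum of squares, m² = 1 − (sum of singular values)², the
correlation sqrt(1 − m²) tested by permuting row order; configurations of
unequal dimensionality are zero-padded.

## Networks

SparCC estimates basis correlations from log-ratio variances
t_ij = var(log x_i/x_j) under sparsity, iteratively excluding the most
correlated pair above `exclusion_threshold` (0.1) from the basis-variance
linear system and re-solving; exclusion stops before any taxon would drop
below two partners.  Component fractions use the Dirichlet posterior mean
(counts + 1), which is deterministic and reproducible; a sampled-fraction
mode (median over `n_outer` Dirichlet draws) mirrors the original
randomized estimator.  Significance comes from a permutation null: each
iteration shuffles every taxon's counts independently across samples —
destroying association, preserving marginals — and recomputes SparCC; the
two-sided exceedance count gives p, floored at 1/(n+1).  p-values are
BH-adjusted across all candidate pairs jointly (within- and cross-kingdom
together; a stratified mode exists).  Edges require |r| above the
kingdom-pair threshold (0.9 within, 0.8 cross) *and* adjusted p < 0.01.
Prevalence filtering defaults to "count > 20 in at least 3 samples"; the
alternative reading ("present in ≥ 3 samples and total > 20") is available
as `mode='presence_total'`.  Diameter and radius are computed on the
largest connected component; heterogeneity is sd(degree)/mean(degree);
hubs are nodes with degree strictly greater than 4.  Degree distributions
are compared by the asymptotic two-sample KS test; degrees are tied
integers, so the p-value is conservative (the calibration test verifies
nominal level on continuous data and non-anti-conservatism on ties).

## Trajectory analysis

A taxon is gradient-responsive when (a) its per-sample relative abundance
exceeds 1 % in at least one sample (the "max" reading of an ambiguous
criterion; an overall-mean mode exists), (b) it is present in strictly more
than 10 samples, and (c) one-way ANOVA of relative abundance across zones
gives p < 0.01 — unadjusted, as stated by the procedure this reproduces,
with a BH option.  ANOVA runs on untransformed relative abundances.  The
selected subset is validated against the full community by protest on
Bray-Curtis PCoA ordinations.  Peak patterns are assigned by a Tukey HSD
(alpha 0.05) decision table — low > both others: group 1; medium and high
each > low and medium ≈ high: group 2; high > both others: group 3;
anything else: "other", never forced — replacing the loosely specified
heatmap clustering with a deterministic rule.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng`; every public
operation takes an explicit seed and is bit-reproducible.  The pipeline
expands one global seed into per-stage children via
`SeedSequence(entropy=seed, spawn_key=(stage_index,))`.  Permutation
p-values always use the +1 estimator.  Validation studies run at
desk-scale sizes (e.g. 2 instances per regime, 199 null replicates, 500
type-I simulations); the acceptance bands were frozen from pilot
Monte-Carlo runs before the corresponding tests were written.

## Known limitations

* betaNTI is uninformative for sample pairs with identical taxon support
  and degenerates on trees without topology (star phylogenies); both cases
  are flagged, not silently classified.
* The RC null estimated from the analysed table itself (the default) is
  mildly biased for small sample sets because occupancy is re-estimated
  from the very communities being tested; the `reference` option removes
  this when a regional pool table exists.
* SparCC's sparsity assumption fails on densely correlated communities;
  the iterative exclusion mitigates but cannot eliminate this.
* The five-process classification inherits the framework's limits: it
  cannot separate diversification from drift inside "undominated", and
  threshold choices (±2, ±0.95) are conventions, not estimated quantities.
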