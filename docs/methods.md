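# Methods

## The problem

Public 16S rRNA gut-microbiome studies sequence one host each: cat and
dog cohorts come from veterinary projects, human cohorts from human
projects.  A classifier that separates pet from human stool samples must
therefore be trained across studies, where project-level batch effects
(collection, extraction, amplification, platform) systematically shift
taxon abundances and can be confounded with the host signal.  This
package implements the full analysis protocol for that setting —
feature-table preparation, project-level differential abundance,
balanced dataset construction, random-forest model selection with
out-of-bag (OOB) evaluation, and a project learning curve that measures
study-level overfitting directly — and exercises it end to end on a
synthetic multi-project generator with known ground truth.

## Feature tables and taxonomy

Input is a samples × genera matrix of integer read counts whose column
identifiers are six-rank lineages (kingdom; phylum; class; order;
family; genus).  Aggregation to a higher rank sums counts over lineage
prefixes and conserves per-sample totals; it is idempotent and composes
(genus→family→phylum equals genus→phylum).  Ranks unresolved by
taxonomy assignment are rendered `unclassified <parent>` so they group
deterministically.  Counts stay integers; relative abundances (fractions
of the per-sample total) are derived on demand and never stored, so a
table cannot be normalized twice.

Rare-feature filtering removes a taxon only when its zero-count sample
fraction is **strictly greater** than 0.9 in the pet class *and* in the
human class ("over 90%" read literally: a taxon at exactly 90% zeros is
kept).  Filtering is monotone in the threshold.

## Chao1 diversity

Per sample, reads are subsampled without replacement (multivariate
hypergeometric) to a fixed depth of 5000 reads, five times; the reported
value is the mean over replicates of the bias-corrected Chao1

    S_chao1 = S_obs + F1 (F1 − 1) / (2 (F2 + 1)),

with S_obs the observed taxa, F1 singletons, F2 doubletons.  The
bias-corrected variant is used because it stays defined at F2 = 0.
Samples shallower than the depth are dropped with a warning rather than
up-sampled.  The Chao value enters the classifier design matrix as one
extra column; it is also tested for a host difference with the same
project-median procedure as the taxa, but never joins the feature sets.

## Project-median differential abundance

Samples within a project share a batch, so the test's replication unit
is the project: per taxon, per-sample relative abundances are reduced to
one median per project and a two-sided Mann-Whitney U test compares pet
project medians (12 under the study layout) with human project medians
(10).  The exact U null is used when both groups have ≤ 12 observations
and the pooled values are tie-free (this covers the 12-vs-10 design);
otherwise the tie-corrected normal approximation with continuity
correction.  Two identical constant vectors give p = 1.

Multiplicity is controlled two ways at α = 0.05 (the conventional
default; configurable): Holm–Bonferroni step-down for family-wise error
and Benjamini–Hochberg step-up for FDR.  Holm rejections are always a
subset of BH rejections at equal α, so the "MW-Holm" feature set is
nested in "MW-FDR".  Both procedures run through
`statsmodels.stats.multitest`; the test suite cross-checks them against
brute-force definitional implementations on random p-vectors, and the
Mann-Whitney p against exhaustive permutation enumeration.

## Transforms

CLR (centered log-ratio): counts + pseudocount (1 read by default) are
closed to proportions and each row is mapped to log x_i − mean_j log x_j
(via scikit-bio).  Rows sum to zero; zero-free rows are scale-invariant
and perturbation-additive.  The pseudocount choice is the simplest
defensible zero replacement; multiplicative replacement would be a
depth-aware alternative but is not the default.  Bray–Curtis
dissimilarity, 1 − 2Σmin(u,v)/(Σu+Σv), supports ordination exports; the
t-SNE embedding itself is plotting glue and is not part of the tested
surface.

## Balanced dataset construction

Training uses equal pet and human sample counts, with the
over-represented class down-sampled so every project contributes as
evenly as possible.  Quotas are filled round-robin (water-filling):
every project's quota rises one sample per round, projects cap out at
their pool size, and the final partial round goes one sample at a time
to the projects with most samples remaining, ties broken by project id.
Applied to the published human project pools
(681, 200, 115, 102, 49, 31, 22, 21, 12, 9) at target 321 this
reproduces the published train-column quotas
(46, 45, 45, 45, 45, 31, 22, 21, 12, 9) exactly — the rule is a
reconstruction, but it reproduces the printed design.  Sampling is
without replacement for model training; the learning curve uses
with-replacement quotas so a few projects can fill the whole class.
Mixed-species evaluation sets (default 100 sets of 200: 50 cats,
50 dogs, 100 humans) are drawn without replacement within a set.

## Random-forest protocol

The design matrix is taxon abundances (fractions, or CLR values)
plus the Chao column; "human" is class 1.  Hyperparameters —
`max_features` (2..p), `max_depth` (2..52), `min_samples_split` (2..52),
`n_estimators` ({1,5,10,50,100,500,1000}) — are selected in two steps
under stratified 5-fold CV mean accuracy:

1. a full Cartesian coarse grid: `max_features` {2, √p, p},
   depth and min-split {2, 12, 32, 52}, trees {10, 100, 500};
2. one-at-a-time fine sweeps (every integer for depth/min-split, a
   25-point geometric ladder for `max_features`, the full tree set),
   each parameter updated before the next is swept.

Ties break toward the simpler model: fewer trees, then shallower, then
larger min-split, then fewer candidate features.  The final forest is
refit 10 times differing only by seed, and OOB accuracy, precision,
recall and F1 are reported as mean ± SD over refits (the replicate unit
behind the "±"; the source protocol does not state its unit, and refits
are the natural one for OOB scores).  Refits = 1 yields SDs of 0 and is
flagged.  If any sample is never out-of-bag the fit errors out rather
than reporting an unstable estimate.  The forest learner is
scikit-learn's; the protocol around it is the contribution.

Feature-importance overlap: with k = |MW set|, the fraction of the top-k
importance-ranked taxa (Chao column excluded) that lie in the MW set.

## Project learning curve

The pet side of training is fixed (all pet samples).  For n = 1..N−1
human projects, combinations are drawn from the first N−1 projects in
sorted order (one project is permanently reserved for testing, matching
the C(N−1, n) bound), min(cap, C(N−1, n)) of them; each combination is
resampled (with replacement, project-balanced quotas) to the fixed
per-class size, a forest with frozen hyperparameters is trained, and
plain accuracy is computed on every human project absent from training.
Hyperparameters are frozen from a prior two-step search rather than
re-searched per resample — the procedure trains hundreds of models and
re-selecting each time would be disproportionate; an override is
available.  Desk-scale defaults are cap 20 and 2 resamples;
`LearningCurveConfig.paper_scale()` restores 200 and 5.  With N = 10
the maximum C(9, n) is 126 < 200, so the "approximately 200 × 5 models
per n" the full protocol describes is not reachable; the min rule is
implemented as stated.

## Synthetic data generator

The generator defines the study conditions for all tests.  Per sample,
taxon t's log-intensity is

    baseline_t + s_host · δ_t/2 + batch_{project,t} + ε_{sample,t}

(s_host = +1 human, −1 pet); the composition is the softmax and counts
are multinomial at a fixed 5000-read depth.  Defaults: 60 genera nested
in 25 families / 18 orders / 12 classes / 8 phyla (catalogue drawn
deterministically from the seed); baseline spread σ = 1.0; 8 planted
genera with |δ| = 3.0 (≈ 20-fold, alternating sign — the scale of
published host-differential genera); one human-exclusive
(Akkermansia-like) and one pet-exclusive (Fusobacterium-like) genus
implemented as hard zeros in the wrong host and placed at low baseline
(−2.5) so detection is depth-limited and imperfect, as for real
low-abundance exclusives; per-(project, taxon) batch shifts
~ Normal(0, σ_batch = 1.0); per-sample noise ~ Normal(0, 1.0).
Log-normal intensities with multinomial counts were chosen over a
Dirichlet-multinomial because every effect is then an explicit,
recoverable ground-truth parameter; overdispersion enters through the
sample noise.  The `paper_like` layout mirrors the published training
design (12 pet projects totalling 321 samples; 10 human projects with
the published train-column sizes, totalling 321); `tiny` is 4+4 projects
× 10 samples for fast tests.

σ_batch = 1.0 is already a strong batch effect (±e² shifts at 2σ): it
reproduces the qualitative learning-curve signature — held-out accuracy
far below the plateau at n = 1, plateau by n ≈ 4–5.  Larger values
(σ_batch = 2) push the plateau past n = 7 and no longer match the
observed phenomenon.

What the generator does **not** emulate: sequencing error, chimeras,
primer and region bias, variable read depth, taxon-taxon correlation
beyond closure, overdispersion structured by phylogeny.  Passing tests
therefore demonstrate that the pipeline recovers the effects it assumes,
not that real cross-study data satisfy those assumptions.

## Numerical and design notes

* All randomness flows from explicit integer seeds; a global run seed
  derives per-stage seeds by hashing the stage name (seeds < 2³¹).
* The null-calibration check uses a 20+20-project layout rather than the
  12-vs-10 design: the exact U null at 12 vs 10 is discrete enough that
  its attainable rejection level at α = 0.05 is 0.0426, at the edge of
  the binomial band the check uses; at 20 vs 20 the attainable level is
  0.0491.  This is a property of rank-test discreteness, not of the
  implementation.
* Degenerate inputs error loudly: all-zero count vectors (Chao),
  all-zero vector pairs (Bray–Curtis), empty feature sets, single-class
  labels, samples never out-of-bag, targets exceeding pools.
* Problem sizes in the test suite (tiny layouts, 20-seed recovery, desk
  scale learning curve with a 50-tree forest) were chosen so that the
  statistical checks retain power while the whole suite stays desk-sized.

## Known limitations

* The quota rule and the two-step coarse grid are reconstructions of an
  underspecified protocol; both are documented choices, not recoveries.
* OOB scores on synthetic data with planted effects sit near 1 and say
  nothing about performance on real sequencing data.
* The exact test's discreteness limits calibration statements for small
  project counts (see above).
* CLR zero handling is a fixed pseudocount; compositional differential
  abundance methods (ANCOM-style) are out of scope.
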