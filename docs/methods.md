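# Methods

## Rank transform

Each sample is summarized by within-sample percentile ranks across its
measured genes: `r_g = (average_rank_g − 0.5) / n`, with tied values given
their average rank and `n` counting the sample's non-missing genes. The
`−0.5` offset makes a tie-free sample a permutation of `(i − 0.5)/n`, a
constant sample map to exactly 0.5, and the scale independent of how many
genes a platform measures. The key property is invariance to any strictly
monotone per-sample transform: CPM/TPM/FPKM scaling, log transforms, and
smooth platform response curves all leave the rank vector unchanged, which
is what makes microarray and RNA-seq samples directly comparable without
any cross-sample normalization. Missing entries stay missing; they are
excluded from `n` for that sample and never imputed at this stage.

This deliberately discards magnitude information: a gene twice as abundant
as another contributes only its ordering. That is the price of
platform-freeness, and it is the assumption behind every downstream step.

## Platform-variance gene filter

Monotone invariance removes *global* platform effects but not *gene-local*
artifacts (probe affinity, GC bias, annotation mismatches) that reorder a
gene relative to its neighbours on one platform. These are detected per
gene by a two-stage decomposition of its rank values across the reference
cohort:

1. subtract each sample's cell-type mean, leaving residuals in which
   biology shared within a cell type has been removed (so a gene that marks
   a cell type profiled mostly on one platform is not punished);
2. compute the between-platform share of the residual variance,
   `fraction = Σ_p n_p · mean_p(resid)² / Σ (resid)²`.

The fraction is 0 when platform means of the residuals coincide, 1 when
residuals are constant within each platform but differ between them, and is
reported as 0 with a degenerate flag when the residuals have no variance at
all. When every cell type is observed on a single platform the statistic
cannot separate platform from biology and a confounding warning is
attached. A gene is kept iff `fraction ≤ θ` **and** it is measured in at
least `min_dataset_frac` of the datasets, where "measured in a dataset"
means non-missing in ≥ 50 % of that dataset's samples.

Defaults: `θ = 0.25` and `min_dataset_frac = 0.9`, chosen for aggressive
platform cleanup — under the simulator's default conditions the residual
between-platform share of a clean gene is of order `1/n_samples` (≈ 0.02 at
48 samples), so 0.25 separates artifact from noise by an order of
magnitude while tolerating moderate platform-cell-type imbalance. Both are
exposed on the CLI. The filter stratifies by cell type only through stage
1; this adjustment is a design choice of this package, recorded in every
bundle manifest alongside the thresholds.

## Atlas model and projection

The kept-gene rank matrix is centered by per-gene mean ranks `μ` and
decomposed by SVD with samples as observations. The top-K right singular
vectors form the loading matrix `L` (columns orthonormal); reference
coordinates are `Lᵀ(r_s − μ)`. `K` defaults to 3 — the reference is meant
to be explored as a 2D/3D scatter — and the achievable rank is checked so
an impossible `K` fails with the attainable value. Sign indeterminacy is
resolved by forcing each column's largest-magnitude loading positive, so
rebuilds are bit-comparable. Samples are not weighted by dataset size: each
sample counts once, so large studies pull the frame proportionally to their
sample count (the alternative — per-dataset weighting — was considered and
not taken, to keep coordinates interpretable as sample variance).

Projection maps an external query into the *frozen* frame: the query is
rank-transformed over its own full measured gene set (never re-ranked after
subsetting, so its coordinates do not depend discontinuously on the atlas
gene list), subset to atlas genes, and centered by the stored `μ`. Atlas
genes the query does not measure are imputed at `μ` — contributing exactly
zero after centering — and counted against a reported coverage fraction;
coverage below 0.5 attaches a warning. Mean-imputation keeps every query in
one coordinate frame; the alternative (dropping genes and re-fitting) would
give each query its own frame and was rejected. There is no re-centering on
the query dataset: this is benchmarking against a fixed reference, not
co-embedding.

Serialized bundles are a directory of `manifest.json` plus TSV matrices;
floats are written with shortest-round-trip repr so `load(save(m))` is
bit-identical. The manifest records the rank convention, duplicate-gene
policy and filter parameters, making bundles self-describing.

## Pseudo-bulk aggregation

Single cells are pooled within each cluster into fixed-size groups (default
eight cells) whose raw counts are summed. Barcodes are shuffled with an
explicit seed and split into consecutive chunks; the final remainder chunk
is kept so rare clusters remain represented, and chunk size and seed are
encoded in the pseudo-sample ids. Summing raw counts rather than averaging
normalized values is deliberate: the rank transform absorbs library-size
differences, and integer conservation (per-gene totals over pseudo-samples
equal totals over cells) is exact. Grouping is random rather than
expression-guided; the seed is exposed.

## Identity scoring

Reference centroids are per-cell-type mean rank vectors over atlas genes.
When the training rank matrix is at hand, centroids are exact means; from a
serialized bundle alone they are reconstructed from the stored low-rank
representation `μ + L·coords`, i.e. the part of each sample's rank vector
the atlas retains (clipped to [0, 1]). Types with fewer than 3 samples are
flagged low-confidence.

* **Correlation mode** reports the Pearson correlation of the query with
  each centroid over shared atlas genes — a similarity score suitable for
  heat maps. The numeric scale is this package's concrete choice.
* **Weight mode** solves `min ‖Cw − q‖², w ≥ 0` (non-negative least
  squares) and normalizes `w` to sum to one, yielding identity weights on
  the probability simplex. The call is the argmax type when its weight
  reaches 0.5 (configurable); otherwise the query is reported as a hybrid
  of its top two types — intermediate phenotypes between two reference
  types are exactly the case this is for. An all-zero NNLS solution (query
  anti-aligned with the positive cone) yields uniform weights and a
  degenerate flag rather than an arbitrary call.

## Differential rank expression

Groups defined by annotation filters are compared per gene with the
two-sided Mann-Whitney-Wilcoxon rank-sum test applied to percentile ranks.
The exact null distribution is used when the smaller group has ≤ 8 samples
and the pooled values are tie-free; otherwise the tie-corrected normal
approximation with continuity correction. P-values are Benjamini-Hochberg
adjusted across genes, and the per-gene platform-variance fraction can be
carried into the table so platform-suspect genes are visible next to their
p-values. The effect measure is `delta_median_rank = median_A − median_B`;
swapping groups negates it and leaves p unchanged.

## Simulator

The generator emulates the statistical structure the method assumes, not
any real myeloid biology:

* per-gene baseline log-means `N(2, 1)` (natural log), with a 25 % marker
  subset receiving per-cell-type effects `N(0, 1)` — the biology to retain;
* log-normal within-type noise, `σ = 0.3`;
* a global monotone platform response `y = a_p · x^{g_p}` (defaults
  `a_p = 1 + p`, `g_p = 1 + 0.15p`) — removed exactly by ranking, by
  construction;
* an additive artifact on a `f = 10 %` platform-sensitive gene subset of
  magnitude `δ = 2` within-type SDs, scaled by platform index (platform 0
  is the unshifted anchor) and applied *before* the monotone response — this
  survives ranking and is what the filter must find;
* an optional additive culture shift on a disjoint 5 % gene subset for
  non-*in vivo* samples (doubled for *in vitro*), off by default, giving the
  sample-source tiers a real transcriptional axis when enabled;
* a single-cell block drawing gamma-Poisson (negative binomial) counts from
  the same cell-type profiles with per-cell log-normal size factors.

Default cohort shape: 2,000 genes, 4 cell types, 4 datasets over 2
platforms, 12 samples per dataset (48 samples), chosen so the full pipeline
runs in seconds while leaving enough degrees of freedom for the
variance decomposition (the null between-platform share ≈ 0.02 sits well
below θ). Datasets are assigned platforms and tiers round-robin so neither
is fully confounded with the other. Shift magnitudes are expressed in
within-type SD units (log-normal moments) so they are comparable across
genes of different abundance. All draws flow from a mandatory seed;
gene-level parameters are drawn first from the bare seed so bulk and
single-cell runs of the same configuration share cell-type profiles.

What the simulator does **not** model — and therefore what passing tests do
not demonstrate about real data: correlated gene modules, compositional
effects, dataset-specific processing pipelines, probe saturation or
non-monotone platform distortions, mixed or ambiguous cell populations, and
real marker structure. It tests the machinery, not the biology.

## Numerical and degenerate-input conventions

* Duplicate gene rows on input are collapsed by per-sample maximum
  (probe-to-gene convention); the policy is recorded in bundle manifests.
* Missing values are NaN throughout; validity constraints apply to
  non-missing entries.
* The platform-variance fraction is clipped to [0, 1] against floating
  error; zero residual variance returns 0 with a degenerate flag.
* PCA uses full SVD (cohorts of this size need no randomized solver), and
  the rank check uses the standard `max(m, n)·eps·σ₁` tolerance.
* Exact/approximate switching in the rank-sum test is at min group size 8,
  a size at which full enumeration is still instant and beyond which the
  normal approximation is conventionally accepted.
* Group filters on the CLI use a `key=value,key=value` syntax over
  annotation columns; contrasts like fresh vs cultured monocytes are
  expressible directly (`"cell_type=monocyte,sample_source=in vivo"`).

## Problem sizes used in tests

The test and acceptance runs use the simulator defaults above (2,000 genes,
48-sample training cohorts; 6 datasets / 3 platforms with one platform held
out for classification checks; 64 cells per type for pseudo-bulk runs, 3,000
cells for the Poisson-limit moment check). These sizes keep the full suite
to a few seconds while giving the seeded regression checks comfortable
margins.

## Known limitations

* Rank space compresses extreme tails; genes near the top or bottom of
  every sample carry little signal after ranking.
* The filter assumes at least two platforms and some sharing of cell types
  across platforms; fully confounded designs are flagged, not fixed.
* Centroids reconstructed from a bundle are low-rank approximations; exact
  centroids require the training rank matrix.
* Mean-imputation of unmeasured atlas genes shrinks low-coverage queries
  toward the origin of the frame; coverage is reported so users can judge.
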