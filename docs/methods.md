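# Methods

This note records the models, numerical conventions and open design
choices behind `scselect`, in the spirit of a statistical software
vignette. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing

RNA counts are log-normalised as `log2(count / s + 1)` with per-cell size
factors `s = total / mean(total)`, so factors average to 1 and a dataset
of equal library sizes is transformed as `log2(count + 1)`. Mass-cytometry
intensities use `asinh(value / cofactor)` with the conventional cofactor
of 5. Both transforms are strictly monotone per feature and leave zeros at
zero. Transform states move one way only (`raw → lognorm|arcsinh →
scaled`); every function declares the state it expects, which catches
double-transformation bugs at the boundary.

PCA is fit on centred, unit-scaled features. Zero-variance features get a
scale factor of 1 (they survive as exact zeros rather than NaNs). The SVD
is computed in full and each component's sign is fixed so its
largest-magnitude loading is positive; together with lexicographic
tie-breaks everywhere downstream, the whole pipeline is deterministic
given a seed. Sparse matrices stay sparse through log-normalisation and
are densified at scaling — a deliberate memory contract: scaling destroys
sparsity anyway.

Stratified splits use largest-remainder rounding of per-type train counts
toward the overall train fraction, with at least one train and one test
cell per type; a type with a single cell is an error, not a warning.

## Active learning

The uncertainty model is either a random forest (500 trees, square-root
feature subsampling) or an L2 logistic regression whose regularisation
strength is chosen by internal stratified 5-fold cross-validation over
`C ∈ {0.01, 0.1, 1, 10}` (plain `C = 1` when a class is too small to
fold). The embedding (20 PCs) is fit once on the whole pool —
transductively — rather than refit per iteration; refitting would change
the feature space every round and make uncertainty scores incomparable
across iterations. The classifier itself is retrained from scratch each
round, with no warm start.

Entropy is base-2 with `0·log 0 := 0`; scaled entropy divides by
`log2 |C|`, where `C` is the set of classes seen in training. Maximum
probability is oriented so that low values mean uncertain.

**Percentile batches.** Selecting "at the 95th/75th percentile" of an
uncertainty distribution is ambiguous; the convention here is: orient
scores so larger = more uncertain, compute the q-th percentile value, and
take the batch of cells at or below that value walking from most to least
uncertain (filling upward past the percentile only if the tail is too
short). `q = 100` degenerates exactly to top-batch-by-uncertainty. Ties
break by ascending cell id. The rule lives behind a single function so an
alternative reading (e.g. a symmetric window) can be swapped in.

**Novel-type reports.** To probe whether entropy reveals an unseen type,
the initial 20-cell set is constructed with exactly 0–3 cells of a chosen
type and the per-type median scaled entropy of all remaining cells is
reported. A genuinely distinct held-out type should show elevated entropy
at 0 copies; a type nearly duplicating a retained one should not — the
retained twin absorbs its cells confidently.

## Adaptive reweighting

Clustering is k-nearest-neighbour (Euclidean, in 30-PC space) → shared
nearest-neighbour graph with Jaccard edge weights (neighbourhoods include
the cell itself; edges below 1/15 pruned) → Leiden modularity optimisation
with a resolution parameter, seeded. This is the same algorithmic family
as the Seurat pipeline it stands in for; exact cluster boundaries are not
expected to match any other implementation, and all downstream contracts
are stated on this clustering.

**Even allocation.** "The same number of cells from each cluster" with
overflow "taken evenly from the others" is implemented as water filling:
find the largest level `T` with `Σ min(size_c, T) ≤ n`, allocate
`min(size_c, T)` everywhere, and hand the remainder one cell at a time to
the lowest-id pools with spare capacity. Consequence: all non-exhausted
pools end within one cell of each other, exhausted pools contribute
everything. The same rule serves the naive (per-cluster) and marker-aware
(per-assigned-type) variants.

**Marker assignment.** Cluster-by-type enrichment is the cluster mean of
per-cell mean positive-marker expression minus mean negative-marker
expression (zero when no negatives are given), computed on the
lognorm/arcsinh scale — pre-scaling, so means are comparable across
markers. Each cluster gets the argmax type, ties broken by marker-file
order; several clusters may share a type (the reason the marker-aware
variant exists), and a type winning no cluster simply receives no pool,
with a logged warning.

## Self-training and mislabel detection

One round only. The confidence statistic is entropy, not maximum
probability. "Top 10/50/100%" applies to the *unlabelled remainder* of
the training pool (only those cells are predicted), rounded half up, ties
by cell id. Oracle labels are never overwritten; pseudo cells carry the
model's argmax label and their scaled entropy at prediction time.

Mislabel detection fits the model on the given (possibly corrupted)
training set and evaluates entropy on those same cells — deliberately not
cross-validated, because the diagnostic of interest is the disagreement
between a cell's label and the model the labels themselves induced.
Label corruption reassigns a seeded uniform sample of cells to a
different class drawn uniformly from the remaining classes.

## Evaluation

The downstream classifier is a random forest behind a
scale → PCA → forest pipeline, grid-searched by stratified 5-fold macro-F1
over `max_features ∈ {4, 6, 10}`, `n_estimators ∈ {100, 150}`, and
`n_pcs ∈ {25, 50}` for RNA or `{20, 39}` for CyTOF, then refit on all
training cells. Folds shrink (with a warning) when the smallest class has
fewer members than folds. Components and feature counts are capped at the
data dimensions, also with a warning.

Metrics: macro-averaged sensitivity and F1 over the classes present in
truth, the Gorodkin multiclass Matthews correlation, Cohen's kappa, and
balanced accuracy (mean per-class recall). Macro averaging is a choice —
it is the imbalance-sensitive convention, consistent with the package's
focus. Cells predicted as `unassigned`/`unknown` are removed from both
vectors before computing anything.

Cell-type similarity is the cosine distance between type centroids in
20-PC space under the inner product weighted by per-component variance
explained. Note a geometric fact: with exactly two types the centroids of
centred data are anti-parallel by construction and the distance is pinned
at 2, so similarity sweeps are only informative with three or more types.

Imbalance designs follow fixed recipes: two-type imbalanced = 450/50,
two-type balanced = 250/250, multi-type imbalanced = 100 from the
majority plus 25 from every minority type, multi-type balanced = 100 per
type (totals therefore depend on the number of types). Marker corruption
replaces a rounded fraction of marker entries (pooled over types and
directions) with random genes from the 10,000 most highly expressed,
excluding everything already in the marker file.

## Synthetic data

The generator is a stated world, not a fit to any real dataset. Per-type
mean vectors start from a shared log-normal baseline (log2 mean 0, sd 1);
each type's `markers_per_type = 5` named markers are up-shifted by
`marker_effect` (log2-fold, default 2), and — because real cell types
differ by broad transcriptional programs, not only curated markers — each
type additionally over-expresses a private program of
`program_genes_per_type = 20` genes at `program_effect = 1` log2-fold.
Similarity links blend one type's mean vector toward another's by a
shared fraction; at 1.0 the two types are identical in expectation, which
is also why heavily shared pairs become genuinely unlearnable rather than
merely hard. RNA counts are negative binomial with size (dispersion) 2;
CyTOF-like intensities are Gaussians with a mean-proportional sd,
truncated at zero. Type assignment is multinomial in the configured
proportions. Fixing the seed fixes every byte.

What a green test on this generator does **not** establish: robustness to
batch effects, doublets, ambient contamination, or dropout beyond NB
zeros — none of which are simulated.

## Fixed worlds used by the acceptance checks

- "Strong markers" means `marker_effect = 3` (8-fold).
- The imbalanced two-type "similar pair" uses a shared fraction of 0.25:
  at 0.5 and above the pair is unlearnable even with full supervision
  (the blend halves every mean difference while NB noise is unchanged),
  which would make any strategy comparison vacuous; 0.25 leaves the pair
  similar (full-data balanced accuracy well below the distinct case) but
  learnable.
- The near-duplicate world for novel-type detection uses a shared
  fraction of 0.9.
- Monte-Carlo checks use 10 fixed seeds and compare medians.

## Known limitations

- The percentile-batch convention and the even-allocation rule are
  reasonable fixations of underspecified procedures; alternatives exist.
- Leiden clustering depends on its seed in near-degenerate cases; all
  contracts are stated on seeded runs.
- External annotation tools (nearest-centroid projections, marker-free
  reference mappers, etc.) are not wrapped; any classifier exposing
  `fit`/`predict_proba` can be plugged into the uncertainty loop, and the
  benchmark's downstream classifier is the custom random forest only.
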