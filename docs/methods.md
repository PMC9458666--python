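# Methods

This note documents the model implemented by `gsnac`, the choices made
where the design was genuinely open, and what the test suite does and does
not establish.

## Model

GSNAc is a supervised classifier for tabular data with any mix of numeric
and categorical features. Its central object is a weighted undirected graph
over the *training samples*: nodes are named by sample id and coloured by
class ("community"), and edge weights are vectorial similarities derived
from a hybrid distance. Classification of a held-out sample is a
neighbourhood vote on this graph rather than a parametric decision rule,
which is what makes every prediction traceable to named training samples.

### Preprocessing

Samples with any missing cell (including a missing class label) are
omitted; no imputation is attempted. Categorical tokens are *labelized* —
mapped to contiguous integer codes in lexicographic token order — rather
than one-hot encoded, so the feature count is unchanged and each
categorical column contributes exactly one term to the distance. Numeric
features are min-max normalized into [0, 1] using bounds fitted on the
training rows only; test values outside the training range clip to the
nearest endpoint, and a feature constant in training maps to 0. Min-max is
preferred over standardization because the subsequent similarity
computation is distance-based and should preserve the shape of
within-feature variation.

### Feature weights

Each feature is scored by the one-way ANOVA F statistic against the class
label, F = (SS_between/(c−1)) / (SS_within/(n−c)), computed on the
transformed (normalized / coded) training columns; the scores, rescaled to
sum to one, are the weight vector of the distance. Conventions for the
degenerate cases: a feature constant across all samples scores 0; a feature
with zero within-class variance but distinct class means would score
infinity, and is assigned the finite sentinel 10¹² so that weight
normalization stays finite (it then dominates the weights, as it should).
Scoring categorical predictors by ANOVA on their integer codes is
statistically crude — the code order is arbitrary — but keeps a single
uniform importance scale across feature kinds; it is a known weak point,
not a claim of optimality. `top_m` optionally retains only the best-scoring
features, intended for tables with thousands of columns; by default all
features are kept.

### Graph construction

The hybrid distance combines a weighted Euclidean part over numeric dims
with a weighted mismatch (L0) part over categorical dims,
dist² = dist_L2² + dist_L0². Distances convert to similarities by
subtraction from the maximum pairwise training distance. Consequences worth
stating explicitly:

- the farthest training pair has similarity exactly 0 and therefore *no*
  edge — the "raw graph" is complete only up to the argmax pair(s);
- ties at the maximum all receive similarity 0; no jitter is added;
- the training maximum is stored in the model and reused at test time, so
  a test sample farther than it from a node clips to similarity 0.

**Pruning** keeps an edge iff it ranks within the k strongest edges of at
least one endpoint (union semantics, the standard kNN-graph construction);
a node can therefore exceed k edges through its neighbours' choices, but
always retains min(k, degree) of its own strongest. Rank ties break by
lexicographic neighbour id for determinism. The effective k is
min(k_max, least-represented class count) with k_max defaulting to 10:
the least-class frequency caps how many same-class neighbours the rarest
class can possibly supply.

**Fortification** injects the supervision into the edge space: surviving
weights are multiplied by (1 + α) for same-class endpoints and (1 − α)
for cross-class ones, α ∈ [0, 1), default 0.5. The map is multiplicative
and symmetric for scale-invariance; α < 1 means no edge is ever deleted,
though the graph may disconnect visually. The result — pruned, fortified,
degree-decorated — is the frozen graph classifier model (GCM). The whole
model path is deterministic: identical inputs give bit-identical GCMs.

### Prediction

A test sample is transformed with the fitted encoder/normalizer (unseen
category tokens get fresh codes above the fitted range, so they mismatch
every training category) and attached to all GCM nodes with vectorial
similarity max(0, max_D − dist). Phase 1 averages each class's up-to-k
strongest similarities and accepts the top class if the relative margin
(s₁ − s₂)/s₁ exceeds the threshold (default 0.01; an absolute-difference
mode is available via `margin_mode="absolute"`). The margin is 1 when only
one class exists and 0 when the best score is 0, so a degenerate phase 1
always falls through. Phase 2 scores each node by the cosine between the
test's similarity profile and that node's fortified edge-weight profile,
both on the common index space of all GCM nodes except the node itself (an
isolated node scores 0), then aggregates per class exactly as phase 1 and
assigns the argmax with no further gate. Residual exact ties break toward
the class with larger GCM support, then the lexicographically smaller
token. Classes absent from the GCM can never be predicted; regression is
out of scope.

Phase-2 aggregation mirrors phase 1's per-class top-k mean. The cosine is
computed between the *full* test profile (minus the node under comparison)
and the node's sparse neighbourhood vector on the same index space; this
keeps both norms on a common basis and the computation deterministic.

## Evaluation harness

Cross-validation uses 2 folds when the least-represented class has fewer
than 10 samples (configurable), else 5 folds — balancing per-fold class
representation against training-graph size. Stratification is a per-class
seeded shuffle followed by round-robin assignment, so per-fold class
proportions are within one sample of the global ones. Every fitted
quantity (normalization bounds, weights, max distance, k, the GCM) is
recomputed per fold from the training rows only. Scoring is the
support-weighted F1; baselines in the benchmark harness are invoked from
scikit-learn (and xgboost when importable) behind a standardization step,
on the identical fold plan, and are never re-implemented here.

## Synthetic data

Two generators double as benchmarks and test fixtures:

- `make_moons_dataset(n=500, noise_sd=0.0, seed)` — two interleaving
  half-circle arcs, n/2 points per class: the upper unit half-circle
  (cos t, sin t) and the shifted lower one (1 − cos t, 0.5 − sin t),
  t evenly spaced on [0, π], plus optional Gaussian jitter. The default is
  noiseless: with the arcs separated by a gap of 0.5 and within-arc
  spacing of π/249 at n = 500, several standard classifiers (and this one)
  reach weighted F1 = 1.0000 under 5-fold CV, which is the intended
  benchmark condition; `noise_sd` exposes harder variants.
- `make_blobs_dataset(n=300, centers=((−3,0),(3,0)), sd=1.0, seed)` —
  isotropic Gaussian clusters, one class per centre, balanced. The default
  centres are six standard deviations apart: well separated but with
  finite overlap in the tails.

These fixtures emulate geometry only. They are balanced, low-dimensional,
noise-free (moons) and feature-independent (blobs); real tabular data has
class imbalance, correlated and irrelevant features, measurement error and
missingness. Passing the synthetic benchmarks therefore validates the
mechanics of the pipeline, not its ranking against other classifiers on
real data.

## Numerical conventions

- Edge existence is a strict `similarity > 0` test; the subtraction
  max_D − dist is exact for the argmax pair, so no tolerance is needed.
- Pairwise distance matrices are symmetrized as (D + Dᵀ)/2 to remove
  floating-point asymmetry from the vectorized computation.
- All tie-breaks (edge ranks, class argmax, category codes) are
  lexicographic or support-based — never random; the only randomness in
  the package is in the synthetic generators, fold shuffling and layout,
  each behind an explicit seed.
- Problem sizes used by the shipped verification runs: the CV benchmark
  uses the generators' default sizes (500 / 300 samples); oracle-agreement
  checks run on hundreds of randomly drawn micro datasets of 3–8 samples,
  where exhaustive loop-based reference implementations are tractable.

## Known limitations

- O(n²) distance and graph work per fold limits training sets to a few
  thousand samples in practice.
- ANOVA-F on labelized categorical codes depends on an arbitrary code
  order (see above).
- The benchmark roster runs baselines with library defaults; no
  hyperparameter search is performed for them or for GSNAc.
- Weighted degree is the only centrality computed; community structure is
  taken from the class labels, never detected.
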