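# Methods

This note records the statistical model behind `graphsep`, the conventions
and numerical choices the implementation commits to, what the synthetic
generator does and does not emulate, and the known limitations.

## The object of study

The package treats each row of a preprocessed table as a point
`x_i ∈ R^d` and asks whether a discrete target `y_i` is *locally
clustered*: do rows of the same class sit among each other's nearest
neighbors? The similarity graph is the measuring instrument — its edges
define "neighbor" — and every separation statistic is a functional of the
labeled graph, so the choice of construction rule (KNN / distance /
cosine) is part of the question being asked, not a nuisance parameter.
KNN graphs fix the local scale adaptively and tend to stay connected;
threshold graphs expose density structure (hubs, outliers) but fragment.

## Preprocessing conventions

- **Role inference** (for columns not declared): a column is numeric iff
  ≥ 95% of its non-missing cells parse as numbers *and* its distinct-value
  ratio (distinct / non-missing) exceeds `numeric_threshold` (default
  0.05). The ratio clause routes low-cardinality integer codes — 0/1
  flags, small ordinal scales — to categorical treatment, which is what
  you want for indicator-style EHR variables.
- **Missing values** (`nan_action`): `drop row` removes rows with a
  missing cell in any *non-ignored* column (an NA in an ignored id should
  not delete a data row). `infer` first drops feature columns whose
  missing ratio exceeds `nan_threshold` (default 0.5), then imputes:
  numeric → mean of observed, categorical and target → most frequent value
  with lexicographic tie-break. `drop col` removes columns above the
  threshold and then any rows still holding missing cells — the contract
  of this stage is a missing-free table, and ratio-based column dropping
  alone cannot guarantee that. Target columns are never dropped by the
  ratio rule.
- **Encoding before scaling.** One-hot keeps *all* categories (no
  reference-level drop), ordered lexicographically on the string
  representation; each encoded row sums to 1 and distances treat
  categories symmetrically. Indicator columns are not re-scaled — they
  already live in [0, 1], and standardizing them would inflate the
  distance contribution of rare categories. Label encoding assigns integer
  codes in lexicographic order.
- **Scaling.** The standard scaler uses the population (n-denominator)
  standard deviation, declared so results are bit-stable; constant columns
  map to zeros with a warning under both scalers.
- **Manifold embedding** (Isomap / t-SNE / UMAP) is computed from the
  scaled numeric block only and is consumed exclusively by the layout
  stage. Graph construction always uses the full preprocessed feature
  space; a test asserts the edge set is identical with and without an
  embedding. t-SNE uses PCA initialization and a perplexity clamped to
  `min(30, (n−1)/3)`; UMAP and t-SNE take `random_seed`, Isomap is
  deterministic.

## Graph construction conventions

- KNN symmetrization is **union**: edge `(u,v)` iff `v` is among `u`'s
  `k` nearest *or* vice versa, so every node keeps degree ≥ k and the
  graph stays connected far more often than under mutual symmetrization.
  The mutual rule is available as a switch (`KNNGraphBuilder(mutual=True)`)
  for sensitivity analysis, since the union convention, while standard,
  is a modeling choice.
- Distance ties at the k-th neighbor break by ascending row index (stable
  argsort), making builds deterministic.
- Both threshold rules use strict inequalities (`< τ` for distance,
  `> s` for similarity). Zero-norm rows have undefined cosine direction;
  their similarity to everything is taken as 0, with a warning.
- Graphs interchange as GraphML with typed attribute keys: `label`
  (string or integer), `manifold_*` and each feature column as double.
  Directed input is accepted and collapsed to undirected with a warning.

## Separation statistics

- **Endpoint counting.** The contingency table `C[i,j]` counts ordered
  edge endpoints (each undirected edge contributes `(u,v)` and `(v,u)`),
  so `C` is symmetric with total `2|E|`. The neighbor-probability matrix
  is the row-normalization of `C`; classes with no incident edges get
  flagged undefined rows rather than silent zeros. The chi-square test
  runs on the same `C` (Pearson, no continuity correction, dof `(c−1)²`),
  keeping the two views of the neighbor structure consistent; the
  identity `homophily = Σ_i P[i,i]·w_i`, with `w_i` class `i`'s share of
  ordered endpoints, is asserted to 1e-12 in the tests. Because the table
  double-counts each edge and edges sharing a node are not independent,
  the chi-square p-value is approximate under the null — adequate for the
  near-zero p-values the statistic is used to report, and the calibration
  test bounds how far from uniform it drifts.
- **Permutation null.** Labels are permuted across nodes with the graph
  fixed, preserving the label multiset. Defaults: 1000 permutations, seed
  42, one-sided (greater) empirical p with add-one smoothing. The
  z-score under random labels is approximately standard normal (verified
  by a 500-draw calibration test); it is reported as NaN with a flag when
  the null has zero spread (single-class graphs).
- **Communities.** Girvan–Newman divisive detection: repeatedly remove
  the highest-edge-betweenness edge (ties broken by lexicographic edge
  id), recording the partition at each increase in component count, up to
  `max_splits` (default 100) recorded splits beyond the initial
  connected-components partition, which is always a candidate. The
  recorded partition with maximal Newman modularity is returned, ties
  going to fewer communities. On fragmented graphs this naturally yields
  community counts near the component count. Community ids are contiguous
  from 0 in decreasing size order.
- **Assortativity.** The headline "assortativity coefficient" is
  Newman's *attribute* assortativity on the target label (the relevant
  quantity in a class-separation context); degree assortativity is
  reported alongside to disambiguate, since the two are easy to conflate.
- **Clustering convention:** nodes of degree < 2 contribute 0 to the
  average clustering coefficient (they are not excluded).

## Visualization choices

Layout uses the manifold coordinates verbatim when present (first two
dimensions; a 1-D embedding is padded with zeros, with a warning),
otherwise a seeded Fruchterman–Reingold force layout. Binary targets are
drawn class 0 = red, class 1 = blue; larger label sets use a categorical
palette keyed by sorted label order. Degree-0 nodes cannot appear on the
log-log degree plot; their count is reported in the figure caption
instead, since isolated nodes are the outlier signal. Figures are PNG at
150 dpi; with `overwrite=false` an existing file is refused with an
explanatory error rather than replaced.

## Synthetic data

`BlobSpec`/`generate_table` emulate a labeled mixed-type table: numeric
columns are unit-variance Gaussians around class centroids placed at the
vertices of a regular simplex scaled so that *every* pairwise centroid
distance equals `separation` (symmetric multi-class control; requires
`n_numeric ≥ n_classes − 1`). Categorical columns draw from
class-conditional category distributions whose sharpness grows with
`separation`, so the one dial controls separability in both blocks.
Missing cells are injected uniformly at the requested rate into feature
columns only, never into the id or target. Everything is deterministic
given the seed.

What this does *not* emulate: correlated features, heteroscedastic or
heavy-tailed noise, class-dependent missingness, measurement error, or
label noise — all present in real clinical tables. Passing the recovery
tests therefore shows the pipeline correctly *reads out* separation that
exists in feature space; it does not show that real EHR data are
separable.

## Problem sizes and defaults in the shipped analyses

The test suite and `scripts/acceptance.py` use n = 500 rows (d = 5,
separation 10) for the recovery readout, 50 and 30 zero-separation
replicates at n = 150 with 200 permutations for null calibration, and
`max_splits` of 3–10 for community detection on the large graphs — on
well-separated blobs the maximal-modularity partition appears within the
first few splits, and Girvan–Newman's repeated betweenness computation is
the dominant cost on dense graphs. These sizes are the package's chosen
study conditions; all statistics scale to larger tables at the usual
O(n²) cost of the distance matrix and O(|V||E|) per betweenness pass.

## Known limitations

- Edges are unweighted; relationship strength below/above the threshold
  is discarded.
- Exact all-pairs distances limit comfortable use to mid-sized tables
  (thousands of rows); no approximate nearest-neighbor index is provided.
- Girvan–Newman is O(|V||E|) per removed edge and dominates runtime on
  dense graphs; `max_splits` caps the work but also caps how deep the
  dendrogram search goes.
- The chi-square independence p-value inherits the dependence caveat
  above; the permutation test is the statistically safer significance
  readout and is preferred in the report.
- Multiple target columns are stored but analysis uses the first, with a
  warning.
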