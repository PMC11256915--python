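# Methods

This note documents the models and procedures implemented in
`spatialcompare`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data generator does and does not
emulate.

## Graph construction

Nodes are cells (single-cell platforms) or spots (array platforms);
node attributes are expression profiles, used exactly as provided — no
normalization is imposed (a `log1p_normalize` helper exists but is off
by default). Coordinates are treated as continuous Euclidean positions;
no pixel/micron rescaling is applied, and all downstream metrics depend
on coordinate scale only through edge weights (which are
expression-space, not physical, distances).

- **Irregular layouts**: Delaunay triangulation, the parameter-free
  default. Duplicate coordinates are rejected (the triangulation is
  undefined on them); a seeded Gaussian `jitter` option is the standard
  fix. Long convex-hull edges are *not* pruned by default, keeping the
  construction parameter-free; `prune_long_edges` is available.
- **Grid layouts**: direct lattice neighbors (≤4 for square, ≤6 for
  hex/offset grids). Off-lattice coordinates raise with a pointer to
  the Delaunay builder.
- kNN and fixed-radius builders exist for completeness but require
  tuning and are never a default.

Cell-type subgraphs are **node-induced** from the full spatial graph:
re-triangulating the subset would invent adjacencies between cells that
were not spatial neighbors in tissue. Subgraphs with fewer than
`min_nodes = 2` cells are skipped in per-type comparisons (a 1-node
graph has a degenerate portrait); the threshold is configurable.

## Network portrait divergence

`B[l,k]` counts nodes with exactly `k` nodes at shortest-path distance
`l` (unit-length paths; edge weights ignored). Row `l=0` is `B[0,N]=…`,
i.e. `B[0,1]=N`; row `l=1` is the degree distribution. Disconnected
graphs are handled through the normalizer `Σ_c n_c²` (ordered reachable
node pairs, including self-pairs), which makes
`P(k,l) = k·B[l,k]/Σ_c n_c²` a proper distribution; unreachable pairs
contribute nothing. The Jensen–Shannon divergence uses base-2
logarithms, the only base for which `D_JS ∈ [0,1]`, with the `0·log 0 = 0`
convention. Portraits are zero-padded to a common shape before
comparison; padding is a no-op on the distribution (verified by test).

The alternative diffusion distance is the supremum over a fixed time
grid (default 0.1, 0.5, 1, 2, 5) of the Frobenius norm between heat
kernels `exp(-tL)` of the two combinatorial Laplacians, zero-padded to
equal size. Padding adds isolated nodes whose kernel block is the
identity in both graphs, so it contributes nothing. Small default grid
values emphasize local structure, larger ones global mixing; the grid is
configurable and the choice is a documented stand-in pending a canonical
formulation.

Per-type results are summarized per condition pair by the mean
divergence across sample pairs, its variance, and an inverse-variance
column (the dot-size confidence weight used in summary plots).

## Differential niche analysis

Per sample, the observed statistic for a type pair `(i,j)` is the number
of edges whose endpoint labels are `{i,j}`; within-type edges count once
per edge, so the upper triangle of the count matrix sums to `|E|`. The
null permutes the label vector uniformly (graph held fixed; the
standard neighborhood-enrichment null — spatially constrained nulls are
out of scope), default 1000 permutations, seeded, vectorized in batches.
Where the permutation sd is zero (e.g. a single label level) the
z-score is defined as 0 and logged.

The m samples' flattened upper triangles (diagonal included —
`n(n+1)/2` entries, ordered row-major `i ≤ j` in lexicographic category
order) form the model response in long format, one observation per
(sample, pair). The design uses **cell-means (no-intercept) coding of
condition × pair** plus batch main-effect dummies (first level
reference); condition contrasts within each pair are computed post hoc
from the coefficient covariance. Family choice: Gaussian (OLS on
z-scores) unless any pair has a zero count in strictly more than 20% of
samples (configurable), in which case a quasi-Poisson GLM (log link) on
the raw counts is used with dispersion estimated by Pearson χ²/df and
t-based inference. Batch is a fixed effect; random-effect models are
out of scope. Both raw and Benjamini–Hochberg-adjusted p-values are
reported, since a single "significant" convention would be arbitrary;
the `significant` flag uses raw p < 0.05.

Rank-deficient designs raise an error listing the aliased columns
(identified by pivoted QR) rather than silently dropping terms.

## Filtration curves

Each sample's weighted graph (edge weight = Euclidean distance between
neighboring expression profiles) is grown over 10 thresholds: the
10th–100th empirical percentiles, linear interpolation (the common
default, fixed for reproducibility), of that sample's own weight
distribution. Per-sample thresholds rather than pooled ones: the
procedure is defined per graph, and condition means then average curves
at matched threshold *indices*. Inclusion is `weight ≤ threshold`, so
tied edges enter together; a node is counted iff incident to at least
one included edge (isolated nodes never appear). Counts are exported
raw and normalized per sample (fraction of the type's final-step
count). Curves are invariant to node reindexing and to any strictly
monotone rescaling of the weights.

## Wasserstein Weisfeiler–Lehman distance

Continuous WL propagation runs `H = 3` iterations by default (the value
recommended in the WWL literature). `deg(v)` is the neighbor count;
isolated nodes (`deg = 0`, where the update is undefined) keep their
attribute, the only fixed-point-consistent choice that does not drop
cells. Edge weights in the update default to 1; the expression-distance
weights can be enabled. The ground metric uses the **concatenation** of
iterations 0…H (the WWL convention; keeping all scales of smoothing),
with final-iteration-only behind a flag. Discrete WL refinement (shared
injective hash table across graphs, isolated nodes keep their label) is
provided for discretely labeled graphs.

Transport uses uniform node masses (no weighting is prescribed by the
method) and is solved **exactly** by default: equal-size graphs reduce
to an assignment problem (with equal uniform marginals an optimal
vertex of the transport polytope is a permutation matrix), solved by
the Jonker–Volgenant algorithm; unequal sizes use the transportation LP
(HiGHS) with one redundant marginal constraint dropped. A log-domain
Sinkhorn approximation (`epsilon` relative to the maximum ground
distance) is available for large samples, along with a seeded
node-subsampling option and a configurable cap (4×10⁶ ground-matrix
entries) that errors with advice rather than exhausting memory. An
optional PCA reduction (50 components) before propagation is available
for very wide feature spaces (tens of thousands of genes), off by
default.

## Group-level tests

Pairwise distances grouped by condition pair are compared with a
two-sample t-test (Student pooled-variance by default, Welch optional,
two-sided — no sidedness is canonical). Distances sharing a sample are
not strictly independent; the test treats them as i.i.d., a caveat
carried in the output (`degenerate_variance` additionally flags
zero-variance groups, where p is set to 1 for equal means and 0
otherwise). Per-cell-type reports BH-adjust across cell types within
each comparison.

## Synthetic data generator

Emulates: uniform spatial point patterns on the unit square, Delaunay
adjacency, multinomial type labels with tunable pairwise mixing,
Gaussian per-type expression signatures (marker-block means, strength
2, noise sd 1), additive per-batch expression shifts (sd 0.2), multiple
samples per condition, full determinism from a master seed (per-sample
seeds spawned from it).

Label mixing: one random-order Gibbs sweep over the Delaunay graph with
`P(label_i = c | neighbors) ∝ proportions[c] · Π_j M[c, label_j]`. The
constant (all-ones) affinity matrix is the multiplicative identity of
this update and the neutral null — labels remain i.i.d. multinomial and
adjacency z-scores are centred at 0 (verified by calibration test). A
single sweep, not run to convergence, is deliberate: cheap, seeded, and
sufficient for a detectable, realistic enrichment signal; it is a
generator property, not an inference claim.

Presets define the study conditions used throughout the tests and the
acceptance script:

- `null` — no condition difference.
- `niche-effect` — condition B triples the `type_0–type_1` affinity;
  batch shifts stay on because the niche model carries a batch term.
- `architecture-effect` — condition B has diagonal affinity 8 (strong
  same-type clustering), in a batch-free 6-samples-per-condition
  cohort of 300-cell samples. Batch-free because the whole-graph
  metrics compare raw expression embeddings with no batch adjustment, so
  per-batch shifts would act as sample-level offsets unrelated to
  architecture; the affinity and cohort size were fixed once, by
  calibration of the generator, so that the preset reliably realizes
  the architecture difference it is named for.

Not emulated: realistic tissue morphology (gradients, layered anatomy),
count-distributed expression (negative binomial / zero inflation),
segmentation noise, spatially varying density. Passing tests therefore
demonstrate correctness of the metrics and calibration of the
statistics under idealized geometry, not robustness to real-data
artifacts.

Model-stage calibration studies (type-I error, effect recovery,
overdispersion detection) simulate enrichment-score designs directly
(`simulate_enrichment_design`) at known ground truth, isolating the
fitting stage from the spatial pipeline.

## Problem sizes and numerical choices

Tests and the acceptance script use 200–300-cell samples, cohorts of up
to 6–10 samples per condition, 200-replicate calibration runs and
50 000-permutation exact-null checks — sizes chosen so the full suite
documents the statistical properties while remaining quick to run on a
laptop. Key tolerances: portrait oracle agreement 1e-10; WL propagation
oracle 1e-12; exact-OT marginal/cost consistency 1e-8; Monte-Carlo
moment checks within 3 standard errors. Ties in Delaunay co-circular
configurations follow the triangulation library's orientation rule (the
unit-square diagonal is not asserted, only the edge count and sides).

## Known limitations

- Portraits use unweighted shortest paths; weighted-path portraits and
  directed graphs are out of scope.
- The t-tests on pairwise distances inherit the dependence caveat
  above; permutation-based group tests are not implemented.
- The quasi-Poisson switch threshold (20% zero-count samples) is a
  convention; it is exposed as a parameter.
- 3-D triangulation and multi-slice stitching are not supported.
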