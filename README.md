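# spatialcompare

Quantitative comparison of cell spatial organization across experimental
conditions in spatial omics data (spatial transcriptomics and
proteomics: imaging-based single-cell panels, spot-based arrays,
high-resolution sequencing-based platforms).

Methods that find spatial structure *within* one tissue section are
plentiful; tools that ask whether the *arrangement* of cells differs
*between* sample groups — disease vs. control, progressor vs.
non-progressor, injured vs. remote tissue — are not. `spatialcompare`
encodes each sample as a spatial proximity graph (nodes = cells or
spots, edges = Delaunay or grid adjacency) and compares samples at three
abstraction levels:

1. **Cell-type-specific subgraphs — network portrait divergence.**
   For each cell type, the node-induced subgraph is summarized by its
   network portrait, the matrix `B[l,k]` counting nodes with exactly `k`
   nodes at shortest-path distance `l`. Portraits are compared through
   the weighted distributions `P(k,l) = k·B[l,k] / Σ_c n_c²` (with `n_c`
   the connected-component sizes) using the Jensen–Shannon divergence
   with base-2 logarithms, `D_JS = ½KL(P‖M) + ½KL(Q‖M)`, `M = (P+Q)/2`,
   so `0 ≤ D_JS ≤ 1`. A heat-kernel diffusion distance is available as
   an alternative metric.
2. **Cellular neighborhoods — differential niche analysis.** Per
   sample, a permutation test yields z-scores for the enrichment of
   adjacent cell-type pairs; the flattened upper triangles
   (`n(n+1)/2` pairs, diagonal included) are stacked across samples and
   modeled with a linear model (or a quasi-Poisson GLM on raw pair
   counts when pairs are sparse), with batch fixed effects and a
   no-intercept condition × pair interaction. t-tests on condition
   contrasts within each pair identify differentially enriched niches.
3. **Entire samples — filtration curves and the Wasserstein
   Weisfeiler–Lehman (WL) distance.** Filtration curves grow each graph
   over 10 edge-weight percentiles (weights = Euclidean distance
   between neighboring expression profiles) and track per-type node
   counts. The WWL distance propagates expression profiles over the
   graph for `H = 3` iterations,
   `a_{h+1}(v) = ½(a_h(v) + 1/deg(v) · Σ_{u∈N(v)} w(v,u)·a_h(u))`,
   and solves the exact optimal transport problem
   `W = min_{T∈Γ} ⟨T, D⟩` between the two embedding clouds under
   uniform node masses.

Group-level questions ("is X organized more like baseline than Y is?")
are answered with two-sample t-tests on the pairwise distances, per cell
type or per sample, with Benjamini–Hochberg adjustment across cell
types.

A fully seeded synthetic-data generator (spatially clustered point
patterns, tunable cell-type mixing via a Gibbs update on the Delaunay
graph, Gaussian per-type expression signatures, batch shifts) makes
every metric testable without external data.

## Worked example

Two synthetic conditions that differ only in tissue architecture
(condition B is strongly assortative — cells cluster with their own
type), 300 cells per sample, six samples per condition:

```python
import spatialcompare as sc

spec, effects = sc.preset("architecture-effect", seed=1, n_cells=300)
dataset = sc.generate_dataset(spec, effects)
graphs = {s.sample_id: sc.build_delaunay(s.coords) for s in dataset}

# whole-sample comparison: Wasserstein WL distances
table = sc.pairwise_wwl(dataset, graphs, all_pairs=True)
ann = sc.annotate_condition_pairs(table, dataset.condition_of())
ann.loc[ann["condition_pair"] != "A|B", "condition_pair"] = "within"
print(ann.groupby("condition_pair")["value"].mean().round(3))

res = sc.compare_distance_groups(ann, "within", "A|B")
print(f"t = {res.t_statistic:.2f}, p = {res.p_value:.2e}")

# cell-type level: portrait divergence, summarized per condition pair
ptab = sc.celltype_divergence(dataset, graphs, metric="portrait")
summary = sc.summarize_celltype_divergence(ptab, dataset.condition_of())
print(summary[summary.cell_type == "type_0"].round(3).to_string(index=False))
```

Output:

```
condition_pair
A|B       4.111
within    3.948
Name: value, dtype: float64
t = -3.82, p = 2.99e-04
cell_type condition_pair  mean  variance  n_pairs  inv_variance
   type_0            A|A 0.109     0.002       15       509.607
   type_0            A|B 0.556     0.031       36        32.622
   type_0            B|B 0.338     0.022       15        45.759
```

Cross-condition samples are farther apart than within-condition samples
under the WWL distance (4.111 vs 3.948, Student's t-test p ≈ 3e-4), and
the portrait divergence for `type_0` subgraphs is low between samples
of the mixed condition A (0.109), higher within the assortative
condition B (0.338) and highest across conditions (0.556); the
`inv_variance` column is the dot-size confidence weight for summary
plots.

The same pipeline runs from the shell:

```sh
spatialcompare synth --preset architecture-effect --outdir demo --seed 1
spatialcompare wwl --input demo/dataset.h5ad --outdir demo_out
spatialcompare portrait --input demo/dataset.h5ad --outdir demo_out
```

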