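"""Network portrait divergence for cell-type-specific subgraphs.

The *network portrait* of a graph is the matrix B whose entry B[l, k]
counts the nodes that have exactly k nodes at shortest-path distance l.
Row l = 0 is degenerate: every node has exactly itself at distance 0, so
B[0, 1] = N.  Row l = 1 is the degree distribution.  The portrait is a
permutation-invariant topology fingerprint: isomorphic graphs share a
portrait, and graphs of different size or connectivity can still be
compared through it.

Two portraits are compared by turning each into a probability
distribution over (k, l),

    P(k, l) = k * B[l, k] / sum_c n_c^2 ,

where n_c are the connected-component sizes (the normalizer counts
ordered reachable node pairs, including self-pairs, which is exactly
sum over l, k of k * B[l, k]), and taking the Jensen-Shannon divergence

    D_JS(P, Q) = 1/2 KL(P || M) + 1/2 KL(Q || M),   M = (P + Q) / 2,

with base-2 logarithms so that 0 <= D_JS <= 1.  D_JS = 0 for isomorphic
graphs; 1 means maximally different portraits.

An alternative diffusion-based distance (sup over a time grid of the
Frobenius norm between heat kernels exp(-t L) of the two zero-padded
graph Laplacians) is provided as a second metric.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from dataclasses import dataclass
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import jensenshannon

from .io_core import Dataset, make_distance_table
from .graphs import SpatialGraph, celltype_subgraph

logger = logging.getLogger("spatialcompare")

__all__ = [
    "NetworkPortrait",
    "compute_portrait",
    "portrait_divergence",
    "diffusion_distance",
    "celltype_divergence",
    "summarize_celltype_divergence",
]

DEFAULT_T_GRID = (0.1, 0.5, 1.0, 2.0, 5.0)


@dataclass
class NetworkPortrait:
    """B[l, k] counts plus component sizes for normalization."""

    B: np.ndarray                 # (L+1, K+1) non-negative integers
    component_sizes: np.ndarray   # (n_components,)

    @property
    def n_nodes(self) -> int:
        return int(self.component_sizes.sum())

    def distribution(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Weighted distribution P(k, l) = k B[l, k] / sum_c n_c^2,
        zero-padded to ``shape`` if given."""
        B = self.B
        if shape is not None:
            out = np.zeros(shape)
            out[: B.shape[0], : B.shape[1]] = B
            B = out
        k = np.arange(B.shape[1])
        P = B * k[None, :]
        return P / float((self.component_sizes ** 2).sum())


def compute_portrait(graph: SpatialGraph) -> NetworkPortrait:
    """Portrait from all-pairs BFS (edge weights ignored; unit paths).

    Unreachable pairs contribute nothing; an edgeless graph has only the
    l = 0 row.
    """
    n = graph.n_nodes
    if n < 1:
        raise ValueError("portrait of an empty graph is undefined")
    A = graph.adjacency()
    n_comp, comp = connected_components(A, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    D = shortest_path(A, method="D", directed=False, unweighted=True)
    finite = np.isfinite(D)
    Dint = np.where(finite, D, -1).astype(np.int64)
    L = int(Dint[finite].max()) if finite.any() else 0
    # per node, number of nodes at each distance l
    B_rows = np.zeros((L + 1, n), dtype=np.int64)
    for i in range(n):
        d = Dint[i][finite[i]]
        cnt = np.bincount(d, minlength=L + 1)
        B_rows[:, i] = cnt
    K = int(B_rows.max())
    B = np.zeros((L + 1, K + 1), dtype=np.int64)
    for l in range(L + 1):
        B[l] = np.bincount(B_rows[l], minlength=K + 1)
    # nodes with zero nodes at distance l are not portrait entries
    B[:, 0] = 0
    return NetworkPortrait(B=B, component_sizes=sizes)


def portrait_divergence(
    ga: SpatialGraph | NetworkPortrait, gb: SpatialGraph | NetworkPortrait
) -> float:
    """Jensen-Shannon divergence (base 2) between two network portraits.

    Accepts graphs or precomputed portraits; returns a value in [0, 1],
    0 for isomorphic graphs.
    """
    pa = ga if isinstance(ga, NetworkPortrait) else compute_portrait(ga)
    pb = gb if isinstance(gb, NetworkPortrait) else compute_portrait(gb)
    shape = (
        max(pa.B.shape[0], pb.B.shape[0]),
        max(pa.B.shape[1], pb.B.shape[1]),
    )
    P = pa.distribution(shape).ravel()
    Q = pb.distribution(shape).ravel()
    d = float(jensenshannon(P, Q, base=2) ** 2)
    # guard tiny negative round-off and the all-equal nan case
    if np.isnan(d):
        d = 0.0
    return min(max(d, 0.0), 1.0)


def diffusion_distance(
    ga: SpatialGraph, gb: SpatialGraph, t_grid=DEFAULT_T_GRID
) -> float:
    """Heat-kernel (graph diffusion) distance.

    sup over t in ``t_grid`` of || exp(-t L_a) - exp(-t L_b) ||_F with the
    combinatorial Laplacians zero-padded to a common size.  Zero padding
    adds isolated nodes, whose heat-kernel block is the identity in both
    graphs, so padding itself contributes nothing.
    """
    t_grid = list(t_grid)
    if not t_grid:
        raise ValueError("t_grid must contain at least one time point")
    n = max(ga.n_nodes, gb.n_nodes)
    if n == 0:
        raise ValueError("diffusion distance of empty graphs is undefined")

    def heat_eigs(g: SpatialGraph):
        L = np.zeros((n, n))
        m = g.n_nodes
        A = g.adjacency().toarray()
        L[:m, :m] = np.diag(A.sum(axis=1)) - A
        lam, V = np.linalg.eigh(L)
        return lam, V

    la, Va = heat_eigs(ga)
    lb, Vb = heat_eigs(gb)
    best = 0.0
    for t in t_grid:
        Ka = (Va * np.exp(-t * la)) @ Va.T
        Kb = (Vb * np.exp(-t * lb)) @ Vb.T
        best = max(best, float(np.linalg.norm(Ka - Kb, "fro")))
    return best


def celltype_divergence(
    dataset: Dataset,
    graphs: dict[str, SpatialGraph],
    metric: str = "portrait",
    min_nodes: int = 2,
    t_grid=DEFAULT_T_GRID,
) -> pd.DataFrame:
    """Distance table over all sample pairs and shared cell types.

    For every unordered sample pair and every cell type with at least
    ``min_nodes`` cells in *both* samples, one row with the chosen metric
    evaluated on the two cell-type subgraphs.  Types absent from either
    sample are skipped with a logged note.
    """
    if metric not in {"portrait", "diffusion"}:
        raise ValueError(f"unknown metric {metric!r}")
    for s in dataset:
        if s.labels is None:
            raise ValueError(f"sample {s.sample_id!r} has no cell-type labels")
    categories = dataset.label_categories

    # precompute subgraphs (and portraits) once per (sample, type)
    subs: dict[tuple[str, str], SpatialGraph] = {}
    ports: dict[tuple[str, str], NetworkPortrait] = {}
    for s in dataset:
        g = graphs[s.sample_id]
        for ct in categories:
            sub = celltype_subgraph(g, s.labels, ct)
            if sub.n_nodes >= min_nodes:
                subs[(s.sample_id, ct)] = sub
                if metric == "portrait":
                    ports[(s.sample_id, ct)] = compute_portrait(sub)

    rows = []
    for sa, sb in itertools.combinations(dataset.sample_ids, 2):
        shared = [
            ct for ct in categories
            if (sa, ct) in subs and (sb, ct) in subs
        ]
        if not shared:
            logger.warning("samples %s and %s share no cell types", sa, sb)
        for ct in shared:
            if metric == "portrait":
                val = portrait_divergence(ports[(sa, ct)], ports[(sb, ct)])
            else:
                val = diffusion_distance(subs[(sa, ct)], subs[(sb, ct)], t_grid)
            rows.append((sa, sb, ct, metric, val))
    return make_distance_table(rows)


def summarize_celltype_divergence(
    table: pd.DataFrame, condition_of: dict[str, str]
) -> pd.DataFrame:
    """Per cell type and condition pair: mean divergence across sample
    pairs, its variance, an inverse-variance confidence column and the
    number of pairs (the dot-plot summary of the per-type results)."""
    df = table.copy()
    ca = df["sample_a"].map(condition_of)
    cb = df["sample_b"].map(condition_of)
    df["condition_pair"] = [
        "|".join(sorted([a, b])) for a, b in zip(ca, cb)
    ]
    out = (
        df.groupby(["cell_type", "condition_pair"])["value"]
        .agg(mean="mean", variance="var", n_pairs="count")
        .reset_index()
    )
    out["variance"] = out["variance"].fillna(0.0)
    with np.errstate(divide="ignore"):
        out["inv_variance"] = np.where(
            out["variance"] > 0, 1.0 / out["variance"], np.inf
        )
    return out
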