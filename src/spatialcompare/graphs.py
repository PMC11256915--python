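"""Spatial adjacency graphs from cell coordinates.

Nodes are cells (or spots); edges encode spatial proximity.  For
irregular layouts the default builder is the Delaunay triangulation,
which is parameter-free: no radius or neighbor count to tune.  Regular
(spot-based) layouts use direct lattice neighbors.  kNN and fixed-radius
builders are provided for completeness but are never the default.

Cell-type-specific subgraphs are node-induced from the full spatial
graph: an edge survives only if both endpoints carry the label.  The
subgraph is *not* re-triangulated on the subset, which would invent
adjacencies between cells that were not spatial neighbors in the tissue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError, cKDTree

logger = logging.getLogger("spatialcompare")

__all__ = [
    "SpatialGraph",
    "build_delaunay",
    "build_grid",
    "build_knn",
    "build_radius",
    "celltype_subgraph",
    "attach_expression_weights",
    "prune_long_edges",
]


@dataclass
class SpatialGraph:
    """Undirected graph over cell rows.

    ``edges`` is an (m, 2) integer array with each edge stored once as
    (u, v), u < v, sorted lexicographically; ``weights`` (optional) is an
    (m,) array aligned with ``edges``.  ``node_ids`` maps node index to
    the row of the originating sample (identity for full graphs).
    """

    n_nodes: int
    edges: np.ndarray
    weights: np.ndarray | None = None
    node_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        e = np.sort(self.edges, axis=1)
        if len(e) and np.any(e[:, 0] == e[:, 1]):
            raise ValueError("self-loops are not allowed")
        order = np.lexsort((e[:, 1], e[:, 0]))
        e = e[order]
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)[order]
        else:
            w = None
        # drop duplicate edges (keep first weight)
        if len(e):
            keep = np.ones(len(e), dtype=bool)
            keep[1:] = np.any(e[1:] != e[:-1], axis=1)
            e = e[keep]
            w = w[keep] if w is not None else None
        self.edges = e
        self.weights = w
        if len(e) and e.max() >= self.n_nodes:
            raise ValueError("edge endpoint out of range")
        if self.node_ids is None:
            self.node_ids = np.arange(self.n_nodes, dtype=np.int64)
        else:
            self.node_ids = np.asarray(self.node_ids, dtype=np.int64)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self, weighted: bool = False) -> sp.csr_matrix:
        """Symmetric sparse adjacency matrix (CSR)."""
        if self.n_edges == 0:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        u, v = self.edges[:, 0], self.edges[:, 1]
        if weighted:
            if self.weights is None:
                raise ValueError("graph has no edge weights attached")
            data = self.weights
        else:
            data = np.ones(self.n_edges)
        A = sp.coo_matrix(
            (np.concatenate([data, data]),
             (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return A.tocsr()

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def neighbor_lists(self) -> list[np.ndarray]:
        A = self.adjacency().tolil()
        return [np.asarray(r, dtype=np.int64) for r in A.rows]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        if self.weights is not None:
            g.add_weighted_edges_from(
                (int(u), int(v), float(w))
                for (u, v), w in zip(self.edges, self.weights)
            )
        else:
            g.add_edges_from((int(u), int(v)) for u, v in self.edges)
        return g

    def edge_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.edges, columns=["node_a", "node_b"])
        df["weight"] = self.weights if self.weights is not None else 1.0
        return df


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _dedupe_or_jitter(coords: np.ndarray, jitter: float, seed: int) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    if np.unique(coords, axis=0).shape[0] != coords.shape[0]:
        raise ValueError(
            "duplicated coordinates; Delaunay triangulation is undefined "
            "on duplicates — pass jitter > 0 to displace them"
        )
    return coords


def build_delaunay(
    coords: np.ndarray, jitter: float = 0.0, seed: int = 0
) -> SpatialGraph:
    """Delaunay triangulation adjacency.

    Fewer than 3 points fall back to the complete graph (with a warning);
    exactly collinear points raise with a hint to use the jitter option.
    """
    coords = _dedupe_or_jitter(coords, jitter, seed)
    n = coords.shape[0]
    if n <= 2:
        warnings.warn(
            f"only {n} point(s); falling back to complete graph", stacklevel=2
        )
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        return SpatialGraph(n_nodes=n, edges=np.array(edges).reshape(-1, 2))
    try:
        tri = Delaunay(coords)
    except QhullError as err:
        raise ValueError(
            "degenerate geometry (e.g. all points collinear); add jitter "
            "to break the degeneracy"
        ) from err
    s = tri.simplices
    edges = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    g = SpatialGraph(n_nodes=n, edges=edges)
    logger.info("Delaunay graph: %d nodes, %d edges", n, g.n_edges)
    return g


def _lattice_indices(x: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Map 1-D coordinates to integer lattice indices or raise."""
    u = np.unique(x)
    if len(u) == 1:
        return np.zeros(len(x), dtype=np.int64)
    step = np.min(np.diff(u))
    idx = (x - u[0]) / step
    r = np.rint(idx)
    if np.max(np.abs(idx - r)) > tol:
        raise ValueError(
            "coordinates are not on a regular lattice; use build_delaunay"
        )
    return r.astype(np.int64)


def build_grid(coords: np.ndarray, layout: str = "square") -> SpatialGraph:
    """Lattice adjacency for spot-based (gridded) layouts.

    ``square``: up to 4 neighbors (lattice index differs by 1 in one
    axis).  ``hex``: up to 6 neighbors (the 4 axis neighbors plus the two
    diagonal neighbors on alternating rows of an offset grid).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if layout == "square":
        ix = _lattice_indices(coords[:, 0])
        iy = _lattice_indices(coords[:, 1])
        index = {(int(a), int(b)): i for i, (a, b) in enumerate(zip(ix, iy))}
        offsets = [(1, 0), (0, 1)]
        edges = []
        for (a, b), i in index.items():
            for da, db in offsets:
                j = index.get((a + da, b + db))
                if j is not None:
                    edges.append((i, j))
    elif layout == "hex":
        # offset rows: connect every pair at (approximately) the minimal
        # point separation; a hex lattice has 6 such neighbors
        tree = cKDTree(coords)
        d, _ = tree.query(coords, k=2)
        dmin = d[:, 1].min()
        pairs = tree.query_pairs(dmin * (1 + 1e-6))
        edges = sorted(pairs)
        deg = np.zeros(n)
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
        if len(edges) == 0 or deg.max() > 6:
            raise ValueError(
                "coordinates do not form a hex lattice; use build_delaunay"
            )
    else:
        raise ValueError(f"unknown layout {layout!r}")
    g = SpatialGraph(n_nodes=n, edges=np.array(edges).reshape(-1, 2))
    logger.info("%s grid graph: %d nodes, %d edges", layout, n, g.n_edges)
    return g


def build_knn(coords: np.ndarray, k: int) -> SpatialGraph:
    """Symmetrized k-nearest-neighbor graph (provided for completeness)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"k must be in [1, n_cells), got {k}")
    tree = cKDTree(coords)
    _, nbr = tree.query(coords, k=k + 1)
    src = np.repeat(np.arange(n), k)
    dst = nbr[:, 1:].ravel()
    return SpatialGraph(n_nodes=n, edges=np.column_stack([src, dst]))


def build_radius(coords: np.ndarray, radius: float) -> SpatialGraph:
    """Fixed-radius proximity graph (provided for completeness)."""
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(radius))
    return SpatialGraph(
        n_nodes=coords.shape[0], edges=np.array(pairs).reshape(-1, 2)
    )


# ---------------------------------------------------------------------------
# Derived graphs
# ---------------------------------------------------------------------------

def celltype_subgraph(
    graph: SpatialGraph, labels, cell_type: str
) -> SpatialGraph:
    """Node-induced subgraph on cells carrying ``cell_type``.

    An absent cell type yields an empty subgraph with a logged warning
    (not an exception) so per-type loops over conditions can proceed.
    """
    labels = pd.Categorical(labels)
    if len(labels) != graph.n_nodes:
        raise ValueError(
            f"{len(labels)} labels for {graph.n_nodes} nodes"
        )
    mask = np.asarray(labels == cell_type)
    if not mask.any():
        logger.warning("cell type %r absent; returning empty subgraph", cell_type)
        return SpatialGraph(n_nodes=0, edges=np.empty((0, 2), dtype=np.int64),
                            node_ids=np.empty(0, dtype=np.int64))
    new_index = -np.ones(graph.n_nodes, dtype=np.int64)
    rows = np.flatnonzero(mask)
    new_index[rows] = np.arange(len(rows))
    if graph.n_edges:
        keep = mask[graph.edges[:, 0]] & mask[graph.edges[:, 1]]
        edges = new_index[graph.edges[keep]]
        w = graph.weights[keep] if graph.weights is not None else None
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        w = None
    return SpatialGraph(
        n_nodes=len(rows), edges=edges, weights=w,
        node_ids=graph.node_ids[rows],
    )


def attach_expression_weights(
    graph: SpatialGraph, expression: np.ndarray
) -> SpatialGraph:
    """Weight each edge by the Euclidean distance between the expression
    profiles of its endpoints."""
    expression = np.asarray(expression, dtype=float)
    if expression.ndim != 2 or expression.shape[0] != graph.n_nodes:
        raise ValueError(
            f"expression leading dimension {expression.shape} does not "
            f"match {graph.n_nodes} nodes"
        )
    if graph.n_edges:
        diff = expression[graph.edges[:, 0]] - expression[graph.edges[:, 1]]
        w = np.linalg.norm(diff, axis=1)
    else:
        w = np.empty(0)
    return SpatialGraph(
        n_nodes=graph.n_nodes, edges=graph.edges.copy(), weights=w,
        node_ids=graph.node_ids.copy(),
    )


def prune_long_edges(
    graph: SpatialGraph, coords: np.ndarray, max_edge_percentile: float
) -> SpatialGraph:
    """Optionally drop the longest edges (e.g. convex-hull spans from the
    Delaunay triangulation).  Not applied by default."""
    coords = np.asarray(coords, dtype=float)
    if graph.n_edges == 0:
        return graph
    lengths = np.linalg.norm(
        coords[graph.edges[:, 0]] - coords[graph.edges[:, 1]], axis=1
    )
    cutoff = np.percentile(lengths, max_edge_percentile)
    keep = lengths <= cutoff
    return SpatialGraph(
        n_nodes=graph.n_nodes,
        edges=graph.edges[keep],
        weights=graph.weights[keep] if graph.weights is not None else None,
        node_ids=graph.node_ids.copy(),
    )
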