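"""Whole-graph comparison with Weisfeiler-Lehman kernels.

Discrete WL refinement repeatedly replaces each node's label with an
injective hash of (own label, sorted multiset of neighbor labels); it is
the classic graph-isomorphism heuristic and is provided for discretely
labeled graphs.

For continuous node attributes (expression profiles) the propagation
scheme is

    a_{h+1}(v) = 1/2 ( a_h(v) + 1/deg(v) * sum_{u in N(v)} w(v, u) a_h(u) ),

iterated H times (default H = 3).  Isolated nodes have no neighbor
average; they keep their attribute (a_{h+1} = a_h), the only choice that
is a fixed point of the update and does not drop cells.  Edge weights
default to 1 (unweighted propagation); the expression-distance weights
can be switched on.

Two graphs are compared by the Wasserstein distance between their node
embedding clouds: the ground distance D[i, j] is the Euclidean distance
between the concatenated embeddings (a_0, ..., a_H) of node i in one
graph and node j in the other, node masses are uniform (1/N), and

    W = min_{T in transport polytope} <T, D>

is solved exactly — as an assignment problem when the two graphs have
equal size (with equal uniform marginals an optimal vertex of the
polytope is a permutation matrix), via the transportation LP otherwise.
An entropic (Sinkhorn) approximation is available for large samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

from .graphs import SpatialGraph
from .io_core import Dataset, SpatialSample, make_distance_table

logger = logging.getLogger("spatialcompare")

__all__ = [
    "WLEmbedding",
    "TransportResult",
    "wl_refine_discrete",
    "wl_propagate_continuous",
    "exact_ot",
    "sinkhorn_ot",
    "wasserstein_wl_distance",
    "pairwise_wwl",
]

DEFAULT_ITERATIONS = 3
DEFAULT_CELL_CAP = 4_000_000  # max N_a * N_b entries of the ground matrix


@dataclass
class WLEmbedding:
    """Per-iteration attribute matrices a_0 ... a_H and their concatenation."""

    iterates: list[np.ndarray]    # H+1 arrays of shape (N, F)

    @property
    def concatenated(self) -> np.ndarray:
        return np.hstack(self.iterates)

    @property
    def final(self) -> np.ndarray:
        return self.iterates[-1]


@dataclass
class TransportResult:
    distance: float
    ground_distances: np.ndarray      # N_a x N_b
    transport_plan: np.ndarray        # N_a x N_b, marginals 1/N_a, 1/N_b


def wl_refine_discrete(
    labels, graph: SpatialGraph, iterations: int,
    label_table: dict | None = None,
) -> list[np.ndarray]:
    """Discrete WL label refinement.

    Returns the label vectors at iterations 0..H as integer codes.  Pass
    the same ``label_table`` dict for every graph in a comparison so that
    identical (label, neighborhood) signatures hash to the same code
    across graphs.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if label_table is None:
        label_table = {}

    def code_of(key) -> int:
        if key not in label_table:
            label_table[key] = len(label_table)
        return label_table[key]

    current = np.array([code_of(("raw", str(l))) for l in labels], dtype=np.int64)
    if len(current) != graph.n_nodes:
        raise ValueError(f"{len(current)} labels for {graph.n_nodes} nodes")
    out = [current.copy()]
    nbrs = graph.neighbor_lists()
    for _ in range(iterations):
        nxt = np.empty_like(current)
        for v in range(graph.n_nodes):
            if len(nbrs[v]) == 0:
                nxt[v] = current[v]   # isolated nodes keep their label
                continue
            sig = (int(current[v]), tuple(sorted(int(current[u]) for u in nbrs[v])))
            nxt[v] = code_of(sig)
        current = nxt
        out.append(current.copy())
    return out


def wl_propagate_continuous(
    features: np.ndarray,
    graph: SpatialGraph,
    iterations: int = DEFAULT_ITERATIONS,
    use_edge_weights: bool = False,
) -> WLEmbedding:
    """Continuous WL propagation of node attributes over the graph."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    a = np.asarray(features, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.shape[0] != graph.n_nodes:
        raise ValueError(
            f"feature matrix has {a.shape[0]} rows for {graph.n_nodes} nodes"
        )
    A = graph.adjacency(weighted=use_edge_weights)
    deg = np.asarray(graph.degrees(), dtype=float)
    isolated = deg == 0
    inv_deg = np.where(isolated, 0.0, 1.0 / np.maximum(deg, 1.0))
    iterates = [a.copy()]
    for _ in range(iterations):
        nbr_avg = (A @ a) * inv_deg[:, None]
        nbr_avg[isolated] = a[isolated]      # identity propagation
        a = 0.5 * (a + nbr_avg)
        iterates.append(a.copy())
    return WLEmbedding(iterates=iterates)


# ---------------------------------------------------------------------------
# Optimal transport
# ---------------------------------------------------------------------------

def exact_ot(D: np.ndarray) -> TransportResult:
    """Exact Wasserstein distance under uniform marginals.

    Equal sizes: assignment problem (Jonker-Volgenant).  Unequal sizes:
    transportation LP solved with HiGHS; one redundant marginal
    constraint is dropped.
    """
    D = np.asarray(D, dtype=float)
    na, nb = D.shape
    if na == nb:
        r, c = linear_sum_assignment(D)
        T = np.zeros_like(D)
        T[r, c] = 1.0 / na
    else:
        c_vec = D.ravel()
        data, rows, cols = [], [], []
        for i in range(na):
            for j in range(nb):
                rows.append(i)
                cols.append(i * nb + j)
                data.append(1.0)
        for j in range(nb - 1):  # last column constraint is redundant
            for i in range(na):
                rows.append(na + j)
                cols.append(i * nb + j)
                data.append(1.0)
        A_eq = sp.coo_matrix(
            (data, (rows, cols)), shape=(na + nb - 1, na * nb)
        ).tocsr()
        b_eq = np.concatenate([np.full(na, 1.0 / na), np.full(nb - 1, 1.0 / nb)])
        res = linprog(c_vec, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
        if not res.success:
            raise RuntimeError(f"transportation LP failed: {res.message}")
        T = res.x.reshape(na, nb)
    return TransportResult(
        distance=float((T * D).sum()), ground_distances=D, transport_plan=T
    )


def sinkhorn_ot(
    D: np.ndarray, epsilon: float = 0.05, max_iter: int = 2000, tol: float = 1e-9
) -> TransportResult:
    """Entropy-regularized OT (log-domain Sinkhorn); approximate."""
    D = np.asarray(D, dtype=float)
    na, nb = D.shape
    scale = D.max() if D.max() > 0 else 1.0
    K = -D / (epsilon * scale)
    log_a = np.full(na, -np.log(na))
    log_b = np.full(nb, -np.log(nb))
    f = np.zeros(na)
    g = np.zeros(nb)
    for _ in range(max_iter):
        f_new = epsilon * scale * (
            log_a - _logsumexp_rows(K + g[None, :] / (epsilon * scale))
        )
        g_new = epsilon * scale * (
            log_b - _logsumexp_rows((K + f_new[:, None] / (epsilon * scale)).T)
        )
        if np.max(np.abs(f_new - f)) < tol and np.max(np.abs(g_new - g)) < tol:
            f, g = f_new, g_new
            break
        f, g = f_new, g_new
    T = np.exp(K + (f[:, None] + g[None, :]) / (epsilon * scale))
    return TransportResult(
        distance=float((T * D).sum()), ground_distances=D, transport_plan=T
    )


def _logsumexp_rows(M: np.ndarray) -> np.ndarray:
    mx = M.max(axis=1, keepdims=True)
    return (mx + np.log(np.exp(M - mx).sum(axis=1, keepdims=True))).ravel()


def wasserstein_wl_distance(
    sample_a: SpatialSample,
    graph_a: SpatialGraph,
    sample_b: SpatialSample,
    graph_b: SpatialGraph,
    iterations: int = DEFAULT_ITERATIONS,
    use_edge_weights: bool = False,
    concatenate: bool = True,
    method: str = "exact",
    epsilon: float = 0.05,
    subsample: int | None = None,
    pca_components: int | None = None,
    cell_cap: int = DEFAULT_CELL_CAP,
    seed: int = 0,
) -> TransportResult:
    """Wasserstein WL distance between two samples.

    ``concatenate`` selects the embedding entering the ground metric:
    the stacked iterations a_0..a_H (default, the WWL convention) or the
    final iterate only.  ``subsample`` caps nodes per sample (uniform,
    seeded) for very large samples.  ``pca_components`` optionally
    projects the two samples' features onto joint principal components
    before propagation (useful for very wide feature spaces; OFF by
    default).
    """
    if sample_a.n_features != sample_b.n_features:
        raise ValueError(
            f"feature dimensions differ: {sample_a.n_features} vs "
            f"{sample_b.n_features}"
        )
    feat_a, feat_b = sample_a.expression, sample_b.expression
    if pca_components is not None and pca_components <= sample_a.n_features:
        joint = np.vstack([feat_a, feat_b])
        centered = joint - joint.mean(axis=0)
        _, _, Vt = np.linalg.svd(centered, full_matrices=False)
        proj = Vt[:pca_components].T
        feat_a = (feat_a - joint.mean(axis=0)) @ proj
        feat_b = (feat_b - joint.mean(axis=0)) @ proj
        logger.info("projected features onto %d joint PCs", pca_components)
    ea = wl_propagate_continuous(feat_a, graph_a, iterations, use_edge_weights)
    eb = wl_propagate_continuous(feat_b, graph_b, iterations, use_edge_weights)
    Xa = ea.concatenated if concatenate else ea.final
    Xb = eb.concatenated if concatenate else eb.final
    if subsample is not None:
        rng = np.random.default_rng(seed)
        if Xa.shape[0] > subsample:
            Xa = Xa[rng.choice(Xa.shape[0], subsample, replace=False)]
        if Xb.shape[0] > subsample:
            Xb = Xb[rng.choice(Xb.shape[0], subsample, replace=False)]
    if Xa.shape[0] * Xb.shape[0] > cell_cap:
        raise ValueError(
            f"ground matrix would have {Xa.shape[0] * Xb.shape[0]} entries "
            f"(cap {cell_cap}); use the subsample option"
        )
    D = cdist(Xa, Xb)
    if method == "exact":
        return exact_ot(D)
    if method == "sinkhorn":
        return sinkhorn_ot(D, epsilon=epsilon)
    raise ValueError(f"unknown method {method!r}")


def pairwise_wwl(
    dataset: Dataset,
    graphs: dict[str, SpatialGraph],
    condition_pairs: list[tuple[str, str]] | None = None,
    all_pairs: bool = False,
    iterations: int = DEFAULT_ITERATIONS,
    **kwargs,
):
    """Distance table of WWL distances.

    With ``condition_pairs``, all cross-condition sample pairs for each
    requested condition pair; with ``all_pairs=True``, every unordered
    sample pair in the dataset (within- and cross-condition).
    """
    cond = dataset.condition_of()
    if condition_pairs is not None:
        known = set(cond.values())
        for a, b in condition_pairs:
            for c in (a, b):
                if c not in known:
                    raise ValueError(f"unknown condition {c!r}")
    wanted = set()
    if all_pairs or condition_pairs is None:
        wanted.update(
            frozenset((a, b))
            for a, b in itertools.combinations(dataset.sample_ids, 2)
        )
    if condition_pairs is not None:
        for ca, cb in condition_pairs:
            ids_a = [s.sample_id for s in dataset.by_condition(ca)]
            ids_b = [s.sample_id for s in dataset.by_condition(cb)]
            for a in ids_a:
                for b in ids_b:
                    if a != b:
                        wanted.add(frozenset((a, b)))
    rows = []
    for pair in sorted(tuple(sorted(p)) for p in wanted):
        a, b = pair
        res = wasserstein_wl_distance(
            dataset.get(a), graphs[a], dataset.get(b), graphs[b],
            iterations=iterations, **kwargs,
        )
        rows.append((a, b, "ALL", "wwl", res.distance))
    logger.info("pairwise_wwl: %d sample pairs", len(rows))
    return make_distance_table(rows)
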