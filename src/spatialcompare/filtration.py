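"""Whole-graph comparison via filtration curves.

A weighted spatial graph (edge weight = Euclidean distance between the
expression profiles of neighboring cells) is grown edge by edge in order
of increasing weight, producing a nested sequence of subgraphs.  At 10
weight thresholds — the 10th, 20th, ..., 100th empirical percentiles of
that sample's own edge weights — we record, per cell type, how many
cells are present in the subgraph.  A node is present iff it is incident
to at least one included edge; isolated nodes are never counted.

The resulting 10 x n_types count matrix is the sample's filtration
curve.  Early steep growth means many low-weight (expression-homogeneous)
neighborhoods, i.e. high density of that type; late growth means the
type joins only through expression-heterogeneous edges.  Curves are
averaged per condition at matched threshold indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import SpatialGraph
from .io_core import Dataset

logger = logging.getLogger("spatialcompare")

__all__ = [
    "FiltrationCurve",
    "filtration_thresholds",
    "filtration_curve",
    "mean_curves",
    "curves_to_frame",
    "dataset_filtration_curves",
]

PERCENTILES = tuple(range(10, 101, 10))


@dataclass
class FiltrationCurve:
    sample_id: str
    condition: str
    thresholds: np.ndarray        # (10,) non-decreasing edge-weight cutoffs
    counts: np.ndarray            # (10, n_types) per-type node counts
    cell_types: list[str]

    def normalized(self) -> np.ndarray:
        """Counts as a fraction of each type's total in this sample's
        final filtration step (types never present stay 0)."""
        totals = self.counts[-1].astype(float)
        totals[totals == 0] = 1.0
        return self.counts / totals


def filtration_thresholds(
    weights: np.ndarray, percentiles=PERCENTILES
) -> np.ndarray:
    """Empirical percentiles (linear interpolation) of the edge weights.

    The last threshold is the 100th percentile, i.e. exactly the maximum
    weight, so the final subgraph is the full weighted graph.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValueError("need at least one edge weight")
    return np.percentile(weights, list(percentiles))


def filtration_curve(
    graph: SpatialGraph, labels, percentiles=PERCENTILES,
    sample_id: str = "", condition: str = "",
) -> FiltrationCurve:
    """Per-type node counts along the weight filtration of one graph."""
    if graph.weights is None:
        raise ValueError(
            "graph has no edge weights; call attach_expression_weights first"
        )
    labels = pd.Categorical(labels)
    if len(labels) != graph.n_nodes:
        raise ValueError(f"{len(labels)} labels for {graph.n_nodes} nodes")
    cats = list(labels.categories)
    codes = np.asarray(labels.codes)
    thr = filtration_thresholds(graph.weights, percentiles)
    counts = np.zeros((len(thr), len(cats)), dtype=np.int64)
    for t, cutoff in enumerate(thr):
        included = graph.edges[graph.weights <= cutoff]
        if len(included):
            nodes = np.unique(included)
            counts[t] = np.bincount(codes[nodes], minlength=len(cats))
    return FiltrationCurve(
        sample_id=sample_id, condition=condition,
        thresholds=thr, counts=counts, cell_types=cats,
    )


def mean_curves(
    curves: list[FiltrationCurve], normalize: bool = False
) -> dict[str, np.ndarray]:
    """Element-wise mean curve per condition at matched threshold index."""
    out: dict[str, list[np.ndarray]] = {}
    for c in curves:
        mat = c.normalized() if normalize else c.counts.astype(float)
        out.setdefault(c.condition, []).append(mat)
    means = {}
    for cond, mats in out.items():
        shapes = {m.shape for m in mats}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent curve shapes in condition {cond!r}")
        means[cond] = np.mean(mats, axis=0)
    return means


def curves_to_frame(curves: list[FiltrationCurve]) -> pd.DataFrame:
    """Long-format export: one row per (sample, threshold, cell type)."""
    rows = []
    for c in curves:
        for t in range(len(c.thresholds)):
            for j, ct in enumerate(c.cell_types):
                rows.append(
                    (
                        c.sample_id, c.condition, t + 1,
                        float(c.thresholds[t]), ct, int(c.counts[t, j]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "condition", "threshold_index",
            "threshold_value", "cell_type", "count",
        ],
    )


def dataset_filtration_curves(
    dataset: Dataset, weighted_graphs: dict[str, SpatialGraph]
) -> list[FiltrationCurve]:
    curves = []
    for s in dataset:
        if s.labels is None:
            raise ValueError(f"sample {s.sample_id!r} has no labels")
        curves.append(
            filtration_curve(
                weighted_graphs[s.sample_id], s.labels,
                sample_id=s.sample_id, condition=s.condition,
            )
        )
    logger.info("computed %d filtration curves", len(curves))
    return curves
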