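"""Group-level statistics on graph distance tables.

The distance tables produced by the portrait and WWL modules hold one
value per sample pair.  To ask questions like "is condition X organized
more like baseline than condition Y is?", the pairwise distances are
grouped by *condition pair* (e.g. baseline|X vs baseline|Y) and the two
groups of distances are compared with a two-sample t-test (Student's
pooled-variance test by default, Welch optional).

Caveat, recorded in the output: pairwise distances within a group share
samples and are therefore not strictly independent; the t-test treats
them as i.i.d. observations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("spatialcompare")

__all__ = [
    "GroupComparison",
    "annotate_condition_pairs",
    "compare_distance_groups",
    "celltype_comparison_report",
]


@dataclass
class GroupComparison:
    grouping_a: str
    grouping_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    test: str
    degenerate_variance: bool = False


def annotate_condition_pairs(
    table: pd.DataFrame, condition_of: dict[str, str]
) -> pd.DataFrame:
    """Add a ``condition_pair`` column ("A|B", sorted) to a distance table."""
    out = table.copy()
    ca = out["sample_a"].map(condition_of)
    cb = out["sample_b"].map(condition_of)
    if ca.isna().any() or cb.isna().any():
        bad = sorted(
            set(out.loc[ca.isna(), "sample_a"]) | set(out.loc[cb.isna(), "sample_b"])
        )
        raise ValueError(f"samples without a condition mapping: {bad}")
    out["condition_pair"] = ["|".join(sorted([a, b])) for a, b in zip(ca, cb)]
    return out


def canonical_pair(a: str, b: str) -> str:
    return "|".join(sorted([a, b]))


def _ttest(values_a: np.ndarray, values_b: np.ndarray, test: str) -> GroupComparison:
    if test not in {"student", "welch"}:
        raise ValueError(f"unknown test {test!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 distance values")
    degenerate = False
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # pooled sd 0: identical means -> no evidence (t=0, p=1);
        # different means -> infinitely strong evidence (p=0), flagged
        degenerate = True
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=(test == "student"))
        t, p = float(t), float(p)
    return GroupComparison(
        grouping_a="", grouping_b="", n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        t_statistic=t, p_value=p, test=test,
        degenerate_variance=degenerate,
    )


def compare_distance_groups(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    test: str = "student",
    cell_type: str | None = None,
) -> GroupComparison:
    """Two-sample t-test between two condition-pair groups of distances.

    ``table`` must carry a ``condition_pair`` column (see
    :func:`annotate_condition_pairs`); ``group_a`` / ``group_b`` are
    condition-pair labels such as ``"control|treated"``.
    """
    if "condition_pair" not in table.columns:
        raise ValueError(
            "table lacks a condition_pair column; call "
            "annotate_condition_pairs first"
        )
    df = table
    if cell_type is not None:
        df = df[df["cell_type"] == cell_type]
    va = df.loc[df["condition_pair"] == group_a, "value"].to_numpy()
    vb = df.loc[df["condition_pair"] == group_b, "value"].to_numpy()
    res = _ttest(va, vb, test)
    res.grouping_a = group_a
    res.grouping_b = group_b
    return res


def celltype_comparison_report(
    table: pd.DataFrame,
    baseline: str,
    alternatives: list[str],
    condition_of: dict[str, str],
    test: str = "student",
) -> pd.DataFrame:
    """Per-cell-type comparison of baseline-vs-X against baseline-vs-Y.

    For every cell type present in both groupings and every unordered
    pair of alternatives, a t-test comparing the distances
    (baseline, alt_1) against (baseline, alt_2); Benjamini-Hochberg
    adjusted p-values are appended across cell types within each
    alternative pair.  Cell types present in only one grouping are
    skipped with a warning.
    """
    if len(alternatives) < 2:
        raise ValueError("need at least two alternative conditions")
    ann = annotate_condition_pairs(table, condition_of)
    rows = []
    for alt1, alt2 in itertools.combinations(alternatives, 2):
        ga = canonical_pair(baseline, alt1)
        gb = canonical_pair(baseline, alt2)
        for ct in sorted(ann["cell_type"].unique()):
            sub = ann[ann["cell_type"] == ct]
            na = (sub["condition_pair"] == ga).sum()
            nb = (sub["condition_pair"] == gb).sum()
            if na < 2 or nb < 2:
                logger.warning(
                    "cell type %r skipped (%d vs %d values)", ct, na, nb
                )
                continue
            r = compare_distance_groups(sub, ga, gb, test=test)
            rows.append(
                {
                    "cell_type": ct,
                    "grouping_a": ga,
                    "grouping_b": gb,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                    "mean_a": r.mean_a,
                    "mean_b": r.mean_b,
                    "t": r.t_statistic,
                    "p": r.p_value,
                    "degenerate_variance": r.degenerate_variance,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = np.nan
        for (ga, gb), idx in out.groupby(["grouping_a", "grouping_b"]).groups.items():
            out.loc[idx, "p_adj"] = multipletests(
                out.loc[idx, "p"], method="fdr_bh"
            )[1]
    return out
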