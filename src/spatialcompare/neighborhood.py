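"""Differential niche analysis: neighborhood enrichment + condition GLMs.

Stage 1 (per sample): a permutation test for neighborhood enrichment.
For an n-type labeling of a spatial graph, the observed statistic for a
type pair (i, j) is the number of edges whose endpoint labels are
{i, j}; within-type edges (i = j) count once per edge.  The null holds
the graph fixed and permutes the label vector uniformly; the z-score is

    z_ij = (obs_ij - mean_perm_ij) / sd_perm_ij ,

with the convention z = 0 where the permutation sd is 0 (degenerate
nulls, e.g. a single label level).

Stage 2 (across samples): the n x n z-score matrix of each sample is
flattened to its upper triangle (diagonal included, so n(n+1)/2 entries)
and the m sample vectors are stacked into an m x n(n+1)/2 response.  A
linear model is fit in long format — one observation per (sample, pair)
— with batch fixed effects and a no-intercept cell-means coding of the
condition x pair interaction; per-coefficient t-tests then ask whether a
pair's enrichment differs between condition levels.  When one or more
pairs are sparse (zero counts in too many samples) the response switches
to the raw pair counts under a quasi-Poisson GLM (log link, dispersion
estimated as Pearson chi^2 / df).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .graphs import SpatialGraph
from .io_core import Dataset

logger = logging.getLogger("spatialcompare")

__all__ = [
    "EnrichmentResult",
    "NicheDesign",
    "NicheFit",
    "nhood_enrichment",
    "flatten_upper",
    "upper_pair_names",
    "choose_family",
    "build_niche_design",
    "fit_niche_model",
    "run_niche_analysis",
]


@dataclass
class EnrichmentResult:
    """Per-sample pair counts and permutation z-scores."""

    categories: list[str]
    pair_counts: np.ndarray   # n x n symmetric ints (observed)
    zscores: np.ndarray       # n x n symmetric
    perm_mean: np.ndarray
    perm_sd: np.ndarray
    n_perms: int
    seed: int


def _pair_count_matrix(codes: np.ndarray, edges: np.ndarray, n_cat: int) -> np.ndarray:
    """Symmetric matrix of adjacent label-pair counts (each edge once)."""
    C = np.zeros((n_cat, n_cat), dtype=np.int64)
    if len(edges):
        a = codes[edges[:, 0]]
        b = codes[edges[:, 1]]
        i = np.minimum(a, b)
        j = np.maximum(a, b)
        np.add.at(C, (i, j), 1)
        C = C + np.triu(C, 1).T
    return C


def nhood_enrichment(
    graph: SpatialGraph,
    labels,
    n_perms: int = 1000,
    seed: int = 0,
    batch_size: int = 512,
) -> EnrichmentResult:
    """Permutation z-scores for adjacent cell-type pair counts."""
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if graph.n_edges < 1:
        raise ValueError("graph has no edges")
    labels = pd.Categorical(labels)
    if len(labels) != graph.n_nodes:
        raise ValueError(f"{len(labels)} labels for {graph.n_nodes} nodes")
    cats = list(labels.categories)
    n_cat = len(cats)
    codes = np.asarray(labels.codes, dtype=np.int64)
    if np.any(codes < 0):
        raise ValueError("labels contain missing values")
    edges = graph.edges

    obs = _pair_count_matrix(codes, edges, n_cat)

    n = graph.n_nodes
    iu = np.triu_indices(n_cat)
    flat_idx = iu[0] * n_cat + iu[1]
    rng = np.random.default_rng(seed)
    sums = np.zeros(len(flat_idx))
    sq_sums = np.zeros(len(flat_idx))
    done = 0
    while done < n_perms:
        chunk = min(batch_size, n_perms - done)
        # chunk x n permutation matrix via argsort of uniforms
        perm = rng.random((chunk, n)).argsort(axis=1)
        lab = codes[perm]                      # chunk x n
        a = lab[:, edges[:, 0]]
        b = lab[:, edges[:, 1]]
        i = np.minimum(a, b)
        j = np.maximum(a, b)
        flat = i * n_cat + j                   # chunk x m
        offset = (np.arange(chunk) * n_cat * n_cat)[:, None]
        counts = np.bincount(
            (flat + offset).ravel(), minlength=chunk * n_cat * n_cat
        ).reshape(chunk, n_cat * n_cat)[:, flat_idx]
        sums += counts.sum(axis=0)
        sq_sums += (counts.astype(float) ** 2).sum(axis=0)
        done += chunk

    mean_flat = sums / n_perms
    var_flat = np.maximum(sq_sums / n_perms - mean_flat ** 2, 0.0)
    sd_flat = np.sqrt(var_flat)

    perm_mean = np.zeros((n_cat, n_cat))
    perm_sd = np.zeros((n_cat, n_cat))
    perm_mean[iu] = mean_flat
    perm_sd[iu] = sd_flat
    perm_mean = perm_mean + np.triu(perm_mean, 1).T
    perm_sd = perm_sd + np.triu(perm_sd, 1).T

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(perm_sd > 0, (obs - perm_mean) / perm_sd, 0.0)
    logger.info(
        "nhood_enrichment: %d nodes, %d edges, %d types, %d perms",
        n, graph.n_edges, n_cat, n_perms,
    )
    return EnrichmentResult(
        categories=cats, pair_counts=obs, zscores=z,
        perm_mean=perm_mean, perm_sd=perm_sd, n_perms=n_perms, seed=seed,
    )


def flatten_upper(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Row-major upper triangle (diagonal included) of a symmetric matrix.

    The pair order is (i, j) with i <= j in category order, so for
    categories (A, B, C): AA, AB, AC, BB, BC, CC.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=atol):
        raise ValueError("matrix is not symmetric")
    iu = np.triu_indices(matrix.shape[0])
    return matrix[iu]


def upper_pair_names(categories: list[str]) -> list[str]:
    iu = np.triu_indices(len(categories))
    return [f"{categories[i]}|{categories[j]}" for i, j in zip(*iu)]


def choose_family(counts: np.ndarray, sparsity_threshold: float = 0.2) -> str:
    """Gaussian on z-scores unless some pair is sparse.

    Returns ``"quasipoisson"`` iff any pair has a zero count in strictly
    more than ``sparsity_threshold`` of the samples.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    zero_frac = (counts == 0).mean(axis=0)
    return "quasipoisson" if np.any(zero_frac > sparsity_threshold) else "gaussian"


@dataclass
class NicheDesign:
    """m x n(n+1)/2 response (z-scores or counts) plus per-sample metadata."""

    response: np.ndarray
    pair_names: list[str]
    sample_ids: list[str]
    condition: list[str]
    batch: list[str] | None
    family: str  # gaussian | quasipoisson

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        m, p = self.response.shape
        n_pairs = len(self.pair_names)
        if p != n_pairs:
            raise ValueError(f"{p} response columns for {n_pairs} pairs")
        # p must be a triangular number n(n+1)/2
        n = int((np.sqrt(8 * p + 1) - 1) / 2)
        if n * (n + 1) // 2 != p:
            raise ValueError(f"{p} pairs is not n(n+1)/2 for any n")
        if not (len(self.sample_ids) == len(self.condition) == m):
            raise ValueError("sample metadata rows do not align with response")
        if self.batch is not None and len(self.batch) != m:
            raise ValueError("batch vector does not align with response")
        if self.family not in {"gaussian", "quasipoisson"}:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class NicheFit:
    """Interaction-model results: per-(condition, pair) cell means and the
    post-hoc condition contrasts within each pair."""

    family: str
    coefficients: pd.DataFrame   # term, estimate, se, t, p
    contrasts: pd.DataFrame      # pair, contrast, estimate, se, t, p, p_adj, significant
    dispersion: float | None
    model_result: object = field(repr=False, default=None)


def build_niche_design(
    dataset: Dataset,
    enrichments: dict[str, EnrichmentResult],
    family: str = "auto",
    sparsity_threshold: float = 0.2,
) -> NicheDesign:
    """Stack per-sample enrichment into the model design.

    ``family="auto"`` applies the sparsity rule of :func:`choose_family`
    to the pair counts; the response is z-scores for the Gaussian family
    and raw pair counts for quasi-Poisson.
    """
    sample_ids = dataset.sample_ids
    first = enrichments[sample_ids[0]]
    pair_names = upper_pair_names(first.categories)
    z = np.vstack([flatten_upper(enrichments[s].zscores) for s in sample_ids])
    counts = np.vstack(
        [flatten_upper(enrichments[s].pair_counts) for s in sample_ids]
    )
    if family == "auto":
        family = choose_family(counts, sparsity_threshold)
        logger.info("choose_family selected %s", family)
    response = counts if family == "quasipoisson" else z
    batches = [s.batch for s in dataset.samples]
    return NicheDesign(
        response=response,
        pair_names=pair_names,
        sample_ids=sample_ids,
        condition=[s.condition for s in dataset.samples],
        batch=None if all(b is None for b in batches) else [b or "" for b in batches],
        family=family,
    )


def _design_matrix(long: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """No-intercept cell-means columns for condition x pair, plus batch
    main-effect dummies (first batch level as reference)."""
    cells = pd.get_dummies(
        long["condition"].astype(str) + ":" + long["pair"].astype(str),
        dtype=float,
    )
    cols = [f"cell[{c}]" for c in cells.columns]
    cells.columns = cols
    X = cells
    if "batch" in long.columns:
        levels = sorted(long["batch"].unique())
        if len(levels) > 1:
            bdum = pd.get_dummies(long["batch"], dtype=float).reindex(
                columns=levels[1:], fill_value=0.0
            )
            bdum.columns = [f"batch[{b}]" for b in levels[1:]]
            X = pd.concat([X, bdum], axis=1)
    return X, cols


def fit_niche_model(design: NicheDesign, alpha: float = 0.05) -> NicheFit:
    """Fit the condition x pair interaction model and test condition
    contrasts within every pair.

    Gaussian family: OLS on z-scores.  Quasi-Poisson: GLM with log link
    on counts, dispersion = Pearson chi^2 / df, t-based inference.
    Contrasts compare each non-baseline condition level against the first
    (sorted) level within each pair; Benjamini-Hochberg adjusted p-values
    are reported alongside the raw ones.
    """
    cond_levels = sorted(set(design.condition))
    if len(cond_levels) < 2:
        raise ValueError("need >= 2 condition levels")
    m, p = design.response.shape

    rows = []
    for si in range(m):
        for pj, pair in enumerate(design.pair_names):
            rows.append(
                {
                    "sample": design.sample_ids[si],
                    "pair": pair,
                    "condition": design.condition[si],
                    "y": design.response[si, pj],
                    **(
                        {"batch": design.batch[si]}
                        if design.batch is not None
                        else {}
                    ),
                }
            )
    long = pd.DataFrame(rows)
    X, cell_cols = _design_matrix(long)
    y = long["y"].to_numpy()

    n_batches = len(set(design.batch)) if design.batch is not None else 1
    if m < n_batches:
        raise ValueError(f"{m} samples for {n_batches} batches")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR
        _, _, piv = _qr_pivots(X.to_numpy())
        aliased = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    if design.family == "gaussian" and len(long) <= X.shape[1]:
        raise ValueError("fewer observations than coefficients")

    if design.family == "gaussian":
        res = sm.OLS(y, X).fit()
        dispersion = None
    else:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(
            scale="X2", use_t=True
        )
        dispersion = float(res.scale)

    coef = pd.DataFrame(
        {
            "term": X.columns,
            "estimate": np.asarray(res.params),
            "se": np.asarray(res.bse),
            "t": np.asarray(res.tvalues),
            "p": np.asarray(res.pvalues),
        }
    )

    baseline = cond_levels[0]
    col_index = {c: i for i, c in enumerate(X.columns)}
    crows = []
    for pair in design.pair_names:
        base_col = f"cell[{baseline}:{pair}]"
        if base_col not in col_index:
            continue
        for level in cond_levels[1:]:
            lev_col = f"cell[{level}:{pair}]"
            if lev_col not in col_index:
                continue
            L = np.zeros(X.shape[1])
            L[col_index[lev_col]] = 1.0
            L[col_index[base_col]] = -1.0
            tt = res.t_test(L)
            crows.append(
                {
                    "pair": pair,
                    "contrast": f"{level}-vs-{baseline}",
                    "estimate": float(np.squeeze(tt.effect)),
                    "se": float(np.squeeze(tt.sd)),
                    "t": float(np.squeeze(tt.tvalue)),
                    "p": float(np.squeeze(tt.pvalue)),
                }
            )
    contrasts = pd.DataFrame(crows)
    if len(contrasts):
        contrasts["p_adj"] = multipletests(contrasts["p"], method="fdr_bh")[1]
        contrasts["significant"] = contrasts["p"] < alpha
    logger.info(
        "fit_niche_model: family=%s, %d obs, %d coefficients, %d contrasts",
        design.family, len(long), X.shape[1], len(contrasts),
    )
    return NicheFit(
        family=design.family,
        coefficients=coef,
        contrasts=contrasts,
        dispersion=dispersion,
        model_result=res,
    )


def _qr_pivots(A: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(A, pivoting=True)
    return Q, R, piv


def run_niche_analysis(
    dataset: Dataset,
    graphs: dict[str, SpatialGraph],
    n_perms: int = 1000,
    seed: int = 0,
    family: str = "auto",
    sparsity_threshold: float = 0.2,
) -> tuple[dict[str, EnrichmentResult], NicheDesign, NicheFit]:
    """End-to-end niche analysis: per-sample enrichment, design, model."""
    enrichments = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(dataset)) % (2 ** 31)
    for s, cseed in zip(dataset, child_seeds):
        enrichments[s.sample_id] = nhood_enrichment(
            graphs[s.sample_id], s.labels, n_perms=n_perms, seed=int(cseed)
        )
    design = build_niche_design(
        dataset, enrichments, family=family,
        sparsity_threshold=sparsity_threshold,
    )
    fit = fit_niche_model(design)
    return enrichments, design, fit
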