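"""Data model, I/O and shared configuration.

A spatial-omics dataset is a collection of tissue sections ("samples").
Each sample carries 2-D cell (or spot) coordinates, a cells x features
expression matrix, optional categorical cell-type labels and metadata
(condition, batch).  Samples are held in :class:`SpatialSample` objects,
grouped into a :class:`Dataset` whose category sets (cell types,
conditions, batches) are unified across samples so that downstream design
matrices are reproducible.

Two on-disk representations are supported: the H5AD annotated-matrix
container (via :mod:`anndata`) and a plain CSV bundle (coordinates,
labels, expression, metadata).  Distance tables produced by the graph
comparison modules are plain CSVs with a fixed header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("spatialcompare")

__all__ = [
    "Config",
    "DEFAULT_CONFIG",
    "SpatialSample",
    "Dataset",
    "DISTANCE_TABLE_COLUMNS",
    "make_distance_table",
    "validate_distance_table",
    "write_distance_table",
    "read_distance_table",
    "read_h5ad",
    "write_h5ad",
    "read_csv_bundle",
    "write_csv_bundle",
    "log1p_normalize",
    "ConfigurationError",
    "FormatError",
]


class ConfigurationError(ValueError):
    """A key or option named by the user does not match the data."""


class FormatError(ValueError):
    """The file content violates the expected format contract."""


@dataclass
class Config:
    """Global defaults shared by all modules.

    Attributes
    ----------
    seed
        Master seed for every randomized operation.
    n_perms
        Number of label permutations in the neighborhood-enrichment null.
    wl_iterations
        Weisfeiler-Lehman refinement depth (default 3, the value
        recommended for the Wasserstein WL kernel).
    n_filtration_thresholds
        Number of edge-weight percentile thresholds for filtration curves
        (default 10: the 10th, 20th, ..., 100th percentiles).
    min_nodes
        Minimum subgraph size for cell-type-specific comparisons.
    sparsity_threshold
        Fraction of samples with a zero pair count above which the niche
        model switches from Gaussian to quasi-Poisson.
    """

    seed: int = 0
    n_perms: int = 1000
    wl_iterations: int = 3
    n_filtration_thresholds: int = 10
    min_nodes: int = 2
    sparsity_threshold: float = 0.2


DEFAULT_CONFIG = Config()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpatialSample:
    """One tissue section: coordinates, expression, labels, metadata.

    Invariants (checked on construction): ``coords`` is N x 2,
    ``expression`` is N x F, ``labels`` (when present) has length N, and
    no two cells share exactly the same coordinates (duplicates make the
    Delaunay triangulation ill-defined).
    """

    sample_id: str
    condition: str
    coords: np.ndarray
    expression: np.ndarray
    labels: pd.Categorical | None = None
    batch: str | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise FormatError(
                f"sample {self.sample_id!r}: coords must be N x 2, "
                f"got shape {self.coords.shape}"
            )
        n = self.coords.shape[0]
        if n < 1:
            raise FormatError(f"sample {self.sample_id!r}: empty sample")
        if self.expression.ndim != 2 or self.expression.shape[0] != n:
            raise FormatError(
                f"sample {self.sample_id!r}: expression leading dimension "
                f"{self.expression.shape} does not match {n} cells"
            )
        if self.labels is not None:
            self.labels = pd.Categorical(self.labels)
            if len(self.labels) != n:
                raise FormatError(
                    f"sample {self.sample_id!r}: {len(self.labels)} labels "
                    f"for {n} cells"
                )
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != n:
            raise FormatError(
                f"sample {self.sample_id!r}: duplicated coordinate rows "
                "(pass jitter to graph construction or deduplicate)"
            )
        if not self.feature_names:
            self.feature_names = [f"feat_{i}" for i in range(self.n_features)]
        if len(self.feature_names) != self.n_features:
            raise FormatError(
                f"sample {self.sample_id!r}: {len(self.feature_names)} "
                f"feature names for {self.n_features} features"
            )

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_features(self) -> int:
        return self.expression.shape[1]

    @property
    def label_categories(self) -> list[str]:
        if self.labels is None:
            return []
        return list(self.labels.categories)


@dataclass
class Dataset:
    """Ordered collection of :class:`SpatialSample` with unified levels."""

    samples: list[SpatialSample]
    condition_levels: list[str] = field(default_factory=list)
    batch_levels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicated sample_id values: {dupes}")
        if not self.condition_levels:
            self.condition_levels = sorted({s.condition for s in self.samples})
        if not self.batch_levels:
            self.batch_levels = sorted(
                {s.batch for s in self.samples if s.batch is not None}
            )
        self._unify_label_categories()

    def _unify_label_categories(self) -> None:
        cats: set[str] = set()
        for s in self.samples:
            cats.update(s.label_categories)
        if not cats:
            return
        shared = sorted(cats)
        for s in self.samples:
            if s.labels is not None:
                s.labels = s.labels.set_categories(shared)

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def label_categories(self) -> list[str]:
        for s in self.samples:
            if s.labels is not None:
                return list(s.labels.categories)
        return []

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def get(self, sample_id: str) -> SpatialSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def condition_of(self) -> dict[str, str]:
        """Map sample_id -> condition."""
        return {s.sample_id: s.condition for s in self.samples}

    def by_condition(self, condition: str) -> list[SpatialSample]:
        return [s for s in self.samples if s.condition == condition]


# ---------------------------------------------------------------------------
# Distance tables
# ---------------------------------------------------------------------------

DISTANCE_TABLE_COLUMNS = ["sample_a", "sample_b", "cell_type", "metric", "value"]

_VALID_METRICS = {"portrait", "diffusion", "wwl"}


def make_distance_table(rows: Sequence[tuple]) -> pd.DataFrame:
    """Build a canonical long-format distance table.

    Each row is ``(sample_a, sample_b, cell_type, metric, value)``;
    ``cell_type`` is ``"ALL"`` for whole-sample metrics.  Sample pairs are
    stored once in canonical (lexicographic) order and rows are sorted.
    """
    df = pd.DataFrame(list(rows), columns=DISTANCE_TABLE_COLUMNS)
    if len(df):
        a = df["sample_a"].astype(str)
        b = df["sample_b"].astype(str)
        swap = a > b
        df.loc[swap, ["sample_a", "sample_b"]] = df.loc[
            swap, ["sample_b", "sample_a"]
        ].to_numpy()
        df = df.sort_values(DISTANCE_TABLE_COLUMNS[:4], kind="mergesort")
        df = df.reset_index(drop=True)
    validate_distance_table(df)
    return df


def validate_distance_table(df: pd.DataFrame) -> None:
    if list(df.columns) != DISTANCE_TABLE_COLUMNS:
        raise FormatError(
            f"distance table columns must be {DISTANCE_TABLE_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    if not len(df):
        return
    bad = set(df["metric"]) - _VALID_METRICS
    if bad:
        raise FormatError(f"unknown metric values: {sorted(bad)}")
    vals = df["value"].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise FormatError("distance values must be non-negative")
    port = df.loc[df["metric"] == "portrait", "value"].to_numpy(dtype=float)
    if len(port) and np.any(port > 1 + 1e-12):
        raise FormatError("portrait divergence values must lie in [0, 1]")


def write_distance_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_distance_table(df)
    out = df.sort_values(DISTANCE_TABLE_COLUMNS[:4], kind="mergesort")
    out.to_csv(path, index=False)
    logger.info("wrote distance table with %d rows to %s", len(out), path)


def read_distance_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in DISTANCE_TABLE_COLUMNS[:4]})
    df["value"] = df["value"].astype(float)
    validate_distance_table(df)
    return df


# ---------------------------------------------------------------------------
# H5AD I/O
# ---------------------------------------------------------------------------

DEFAULT_KEYS = {
    "sample": "sample",
    "condition": "condition",
    "batch": "batch",
    "label": "cell_type",
    "coord": "spatial",
}


def read_h5ad(
    path: str | Path,
    keys: Mapping[str, str] | None = None,
    require_labels: bool = True,
) -> Dataset:
    """Read a Dataset from an annotated-matrix (H5AD) file.

    ``keys`` maps the roles ``sample``, ``condition``, ``batch``, ``label``
    to observation columns and ``coord`` to the obsm slot holding the 2-D
    spatial coordinates.  ``batch`` is optional; ``label`` is optional when
    ``require_labels`` is false.
    """
    import anndata as ad

    key = dict(DEFAULT_KEYS)
    if keys:
        key.update(keys)
    adata = ad.read_h5ad(path)

    for role in ("sample", "condition"):
        if key[role] not in adata.obs.columns:
            raise ConfigurationError(
                f"observation column {key[role]!r} (role {role!r}) not found; "
                f"available: {list(adata.obs.columns)}"
            )
    if key["coord"] not in adata.obsm:
        raise ConfigurationError(
            f"coordinate slot {key['coord']!r} not found in obsm; "
            f"available: {list(adata.obsm)}"
        )
    coords = np.asarray(adata.obsm[key["coord"]], dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise FormatError(
            f"coordinates in {key['coord']!r} must be N x 2, got {coords.shape}"
        )
    has_labels = key["label"] in adata.obs.columns
    if require_labels and not has_labels:
        raise ConfigurationError(
            f"label column {key['label']!r} not found "
            "(pass require_labels=False for label-free analyses)"
        )
    has_batch = key["batch"] in adata.obs.columns

    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    feature_names = [str(v) for v in adata.var_names]

    samples = []
    sample_col = adata.obs[key["sample"]].astype(str)
    for sid in sorted(sample_col.unique()):
        mask = (sample_col == sid).to_numpy()
        cond = str(adata.obs.loc[mask, key["condition"]].iloc[0])
        batch = str(adata.obs.loc[mask, key["batch"]].iloc[0]) if has_batch else None
        labels = (
            pd.Categorical(adata.obs.loc[mask, key["label"]].astype(str))
            if has_labels
            else None
        )
        samples.append(
            SpatialSample(
                sample_id=sid,
                condition=cond,
                batch=batch,
                coords=coords[mask],
                expression=X[mask],
                labels=labels,
                feature_names=list(feature_names),
            )
        )
    ds = Dataset(samples=samples)
    logger.info(
        "read %d samples (%d cells total) from %s",
        len(ds), sum(s.n_cells for s in ds), path,
    )
    return ds


def write_h5ad(dataset: Dataset, path: str | Path, keys: Mapping[str, str] | None = None) -> None:
    """Write a Dataset to H5AD with the same conventions read_h5ad expects."""
    import anndata as ad

    key = dict(DEFAULT_KEYS)
    if keys:
        key.update(keys)
    X = np.vstack([s.expression for s in dataset.samples])
    coords = np.vstack([s.coords for s in dataset.samples])
    obs = pd.DataFrame(
        {
            key["sample"]: np.concatenate(
                [[s.sample_id] * s.n_cells for s in dataset.samples]
            ),
            key["condition"]: np.concatenate(
                [[s.condition] * s.n_cells for s in dataset.samples]
            ),
        }
    )
    if any(s.batch is not None for s in dataset.samples):
        obs[key["batch"]] = np.concatenate(
            [[s.batch or ""] * s.n_cells for s in dataset.samples]
        )
    if any(s.labels is not None for s in dataset.samples):
        obs[key["label"]] = np.concatenate(
            [np.asarray(s.labels).astype(str) for s in dataset.samples]
        )
    obs.index = [f"cell_{i}" for i in range(len(obs))]
    var = pd.DataFrame(index=dataset.samples[0].feature_names)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.obsm[key["coord"]] = coords
    adata.write_h5ad(Path(path))


# ---------------------------------------------------------------------------
# CSV bundle I/O
# ---------------------------------------------------------------------------

def read_csv_bundle(
    coords_path: str | Path,
    labels_path: str | Path | None,
    expression_path: str | Path,
    metadata_path: str | Path,
) -> Dataset:
    """Read a Dataset from a CSV bundle.

    Files share a ``cell_id`` column: ``coords`` (cell_id, sample_id, x, y),
    ``labels`` (cell_id, cell_type; optional file), ``expression`` (cell_id
    plus one column per feature) and ``metadata`` (sample_id, condition
    [, batch]).
    """
    coords = pd.read_csv(
        coords_path, dtype={"cell_id": str, "sample_id": str},
        float_precision="round_trip",
    )
    expr = pd.read_csv(
        expression_path, dtype={"cell_id": str}, float_precision="round_trip"
    )
    meta = pd.read_csv(metadata_path, dtype=str).set_index("sample_id")

    for frame, name in ((expr, "expression"),):
        missing = set(coords["cell_id"]) ^ set(frame["cell_id"])
        if missing:
            raise FormatError(
                f"cell ids in {name} CSV do not match coordinates; first "
                f"offending id: {sorted(missing)[0]!r}"
            )
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path, dtype=str)
        missing = set(coords["cell_id"]) ^ set(labels["cell_id"])
        if missing:
            raise FormatError(
                f"cell ids in labels CSV do not match coordinates; first "
                f"offending id: {sorted(missing)[0]!r}"
            )
        labels = labels.set_index("cell_id")
    expr = expr.set_index("cell_id")
    feature_names = list(expr.columns)

    samples = []
    for sid, grp in coords.groupby("sample_id", sort=True):
        cell_ids = grp["cell_id"].tolist()
        if sid not in meta.index:
            raise FormatError(f"sample {sid!r} missing from metadata CSV")
        row = meta.loc[sid]
        samples.append(
            SpatialSample(
                sample_id=str(sid),
                condition=str(row["condition"]),
                batch=str(row["batch"]) if "batch" in meta.columns else None,
                coords=grp[["x", "y"]].to_numpy(dtype=float),
                expression=expr.loc[cell_ids].to_numpy(dtype=float),
                labels=(
                    pd.Categorical(labels.loc[cell_ids, "cell_type"])
                    if labels is not None
                    else None
                ),
                feature_names=feature_names,
            )
        )
    return Dataset(samples=samples)


def write_csv_bundle(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write a Dataset as a CSV bundle readable by :func:`read_csv_bundle`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cell_ids, rows_c, rows_l = [], [], []
    for s in dataset.samples:
        for i in range(s.n_cells):
            cid = f"{s.sample_id}:{i}"
            cell_ids.append(cid)
            rows_c.append((cid, s.sample_id, s.coords[i, 0], s.coords[i, 1]))
            if s.labels is not None:
                rows_l.append((cid, str(s.labels[i])))
    paths = {
        "coords": outdir / "coords.csv",
        "expression": outdir / "expression.csv",
        "metadata": outdir / "metadata.csv",
    }
    # %.17g round-trips float64 exactly
    pd.DataFrame(rows_c, columns=["cell_id", "sample_id", "x", "y"]).to_csv(
        paths["coords"], index=False, float_format="%.17g"
    )
    expr = pd.DataFrame(
        np.vstack([s.expression for s in dataset.samples]),
        columns=dataset.samples[0].feature_names,
    )
    expr.insert(0, "cell_id", cell_ids)
    expr.to_csv(paths["expression"], index=False, float_format="%.17g")
    meta = pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "condition": [s.condition for s in dataset.samples],
        }
    )
    if any(s.batch is not None for s in dataset.samples):
        meta["batch"] = [s.batch or "" for s in dataset.samples]
    meta.to_csv(paths["metadata"], index=False)
    if rows_l:
        paths["labels"] = outdir / "labels.csv"
        pd.DataFrame(rows_l, columns=["cell_id", "cell_type"]).to_csv(
            paths["labels"], index=False
        )
    logger.info("wrote CSV bundle to %s", outdir)
    return paths


def log1p_normalize(sample: SpatialSample, target_sum: float = 1e4) -> SpatialSample:
    """Optional total-count + log1p normalization helper (OFF by default).

    Expression values are otherwise used exactly as provided.
    """
    totals = sample.expression.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    X = np.log1p(sample.expression / totals * target_sum)
    return replace(sample, expression=X)
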