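"""Data model, file readers/writers and run configuration.

Supported formats: 10x-style MatrixMarket triplets (matrix.mtx +
features.tsv + barcodes.tsv), dense spot-by-gene CSV, h5ad containers
(read-only), Visium tissue-positions CSV (5- or 6-column dialects) or
generic ``spot_id,x,y`` tables, and two-column label CSVs.
"""

from __future__ import annotations

import csv
import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("stclust")

VARIANTS = ("G", "GS", "GN", "Scatter", "ACT", "FACT")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the requested format."""


class EmptyIntersectionError(ValueError):
    """Raised when counts and positions share no spot barcodes."""


@dataclass
class SpatialDataset:
    """Spot-by-gene counts with coordinates, identifiers and optional labels.

    counts : (n_spots, n_genes) non-negative matrix
    coords : (n_spots, 2) planar positions (lattice or pixel units)
    spot_ids / gene_ids : unique string identifiers
    truth_labels : optional per-spot categorical labels (evaluation only)
    extra_features : named (n_spots, d) feature blocks, e.g. image embeddings
    """

    counts: np.ndarray
    coords: np.ndarray
    spot_ids: list
    gene_ids: list
    truth_labels: Optional[np.ndarray] = None
    extra_features: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.spot_ids = list(self.spot_ids)
        self.gene_ids = list(self.gene_ids)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts contains negative entries")
        n, p = self.counts.shape
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot_ids for {n} rows")
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {p} columns")
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords must be ({n}, 2), got {self.coords.shape}")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot_ids")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene_ids")
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels)
            if len(self.truth_labels) != n:
                raise ValueError("truth_labels length does not match n_spots")
        for name, block in self.extra_features.items():
            if np.asarray(block).shape[0] != n:
                raise ValueError(f"extra feature block {name!r} row mismatch")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, index: np.ndarray) -> "SpatialDataset":
        index = np.asarray(index)
        return SpatialDataset(
            counts=self.counts[index],
            coords=self.coords[index],
            spot_ids=[self.spot_ids[i] for i in index],
            gene_ids=list(self.gene_ids),
            truth_labels=None if self.truth_labels is None else self.truth_labels[index],
            extra_features={k: np.asarray(v)[index] for k, v in self.extra_features.items()},
        )

    def subset_genes(self, index: np.ndarray) -> "SpatialDataset":
        index = np.asarray(index)
        return SpatialDataset(
            counts=self.counts[:, index],
            coords=self.coords,
            spot_ids=list(self.spot_ids),
            gene_ids=[self.gene_ids[i] for i in index],
            truth_labels=self.truth_labels,
            extra_features=dict(self.extra_features),
        )


@dataclass
class RunConfig:
    """Top-level configuration for a clustering run.

    Randomness throughout the pipeline flows from ``seed`` expanded into
    per-stage substreams, so a run is bit-reproducible given (inputs, config).
    """

    variant: str = "ACT"
    n_clusters: int = 7
    latent_dim: int = 32
    k_neighbors: int = 6
    seed: int = 0
    n_hvg: int = 3000
    keep_fraction: float = 1.0
    filtration: object = None
    normalization: object = None
    training: object = None
    gmm: object = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not (0.0 < self.keep_fraction <= 1.0):
            raise ValueError("keep_fraction must be in (0, 1]")
        from .preprocess import FiltrationConfig, NormalizationConfig
        from .representation import TrainingConfig
        from .domain_clustering import GMMConfig

        if self.filtration is None:
            self.filtration = FiltrationConfig(seed=self.seed)
        if self.normalization is None:
            self.normalization = NormalizationConfig()
        if self.training is None:
            self.training = TrainingConfig(seed=self.seed)
        if self.gmm is None:
            self.gmm = GMMConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        from .preprocess import FiltrationConfig, NormalizationConfig
        from .representation import TrainingConfig
        from .domain_clustering import GMMConfig

        nested = {
            "filtration": FiltrationConfig,
            "normalization": NormalizationConfig,
            "training": TrainingConfig,
            "gmm": GMMConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested and isinstance(value, dict):
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def substream(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage RNG derived from the run seed."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return np.random.default_rng(ss)


def _open_maybe_gzip(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _find_companion(directory: str, stems: Sequence[str]) -> str:
    for stem in stems:
        for suffix in ("", ".gz"):
            candidate = os.path.join(directory, stem + suffix)
            if os.path.exists(candidate):
                return candidate
    raise FormatError(f"no companion file among {stems} in {directory}")


def read_positions(path: str, keep_filtered: bool = False) -> pd.DataFrame:
    """Read a positions table into columns (spot_id, x, y).

    Accepts the 5/6-column Visium tissue-positions dialects (with the
    in_tissue flag; rows with in_tissue == 0 dropped unless keep_filtered)
    and generic ``spot_id,x,y`` tables. A header row is auto-detected.
    """
    try:
        first = pd.read_csv(path, header=None, nrows=1)
    except Exception as exc:  # pragma: no cover - passthrough formatting
        raise FormatError(f"cannot read positions file {path}: {exc}") from exc
    has_header = False
    if first.shape[1] >= 2:
        try:
            float(first.iloc[0, 1])
        except (TypeError, ValueError):
            has_header = True
    df = pd.read_csv(path, header=0 if has_header else None)
    ncols = df.shape[1]
    if ncols == 3:
        out = pd.DataFrame(
            {
                "spot_id": df.iloc[:, 0].astype(str),
                "x": df.iloc[:, 1].astype(float),
                "y": df.iloc[:, 2].astype(float),
            }
        )
    elif ncols in (5, 6):
        # Visium dialect: barcode, in_tissue, array coords, pixel row, pixel col.
        out = pd.DataFrame(
            {
                "spot_id": df.iloc[:, 0].astype(str),
                "in_tissue": df.iloc[:, 1].astype(int),
                "x": df.iloc[:, ncols - 1].astype(float),
                "y": df.iloc[:, ncols - 2].astype(float),
            }
        )
        if not keep_filtered:
            dropped = int((out["in_tissue"] == 0).sum())
            if dropped:
                logger.info("dropping %d positions with in_tissue=0", dropped)
            out = out[out["in_tissue"] != 0]
        out = out[["spot_id", "x", "y"]]
    else:
        raise FormatError(f"positions table has {ncols} columns; expected 3, 5 or 6")
    if out["spot_id"].duplicated().any():
        raise FormatError("duplicate spot ids in positions table")
    return out.reset_index(drop=True)


def _load_mtx10x(counts_path: str):
    from scipy.io import mmread

    directory = os.path.dirname(os.path.abspath(counts_path))
    features_path = _find_companion(directory, ["features.tsv", "genes.tsv"])
    barcodes_path = _find_companion(directory, ["barcodes.tsv"])
    try:
        mat = mmread(counts_path)
    except Exception as exc:
        raise FormatError(f"cannot parse MatrixMarket file {counts_path}: {exc}") from exc
    counts = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    with _open_maybe_gzip(features_path) as fh:
        features = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gzip(barcodes_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    if counts.shape == (len(features), len(barcodes)):
        counts = counts.T  # 10x convention stores genes x barcodes
    elif counts.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"matrix shape {counts.shape} does not match "
            f"{len(barcodes)} barcodes x {len(features)} features"
        )
    return counts, barcodes, features


def _load_dense_csv(counts_path: str):
    with open(counts_path) as fh:
        header = next(csv.reader(fh))
    gene_names = header[1:]
    if len(set(gene_names)) != len(gene_names):
        raise FormatError("duplicate gene column names in dense CSV")
    df = pd.read_csv(counts_path, index_col=0)
    return df.to_numpy(dtype=float), [str(s) for s in df.index], gene_names


def _load_h5ad(counts_path: str):
    import anndata

    try:
        adata = anndata.read_h5ad(counts_path)
    except Exception as exc:
        raise FormatError(f"cannot read h5ad container {counts_path}: {exc}") from exc
    X = adata.X
    if hasattr(X, "todense"):
        X = np.asarray(X.todense())
    return np.asarray(X), [str(s) for s in adata.obs_names], [str(g) for g in adata.var_names]


def load_dataset(
    counts_path: str,
    positions_path: str,
    format: str = "mtx10x",
    keep_filtered: bool = False,
) -> SpatialDataset:
    """Load counts + positions into a SpatialDataset.

    Spot order follows the barcode order of the counts file restricted to
    barcodes present in the positions table; spots missing from either
    source are dropped with a logged count.
    """
    loaders = {"mtx10x": _load_mtx10x, "dense_csv": _load_dense_csv, "h5ad": _load_h5ad}
    if format not in loaders:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(loaders)}")
    counts, barcodes, genes = loaders[format](counts_path)
    positions = read_positions(positions_path, keep_filtered=keep_filtered)
    pos_map = {sid: (x, y) for sid, x, y in positions.itertuples(index=False)}
    keep = [i for i, b in enumerate(barcodes) if b in pos_map]
    if not keep:
        raise EmptyIntersectionError("no overlapping spots between counts and positions")
    n_dropped = (len(barcodes) - len(keep)) + (len(pos_map) - len(keep))
    if n_dropped:
        logger.warning("dropped %d spots absent from counts/positions intersection", n_dropped)
    spot_ids = [barcodes[i] for i in keep]
    coords = np.array([pos_map[s] for s in spot_ids], dtype=float)
    return SpatialDataset(
        counts=counts[keep], coords=coords, spot_ids=spot_ids, gene_ids=genes
    )


_LABEL_HEADER_TOKENS = {"spot", "spot_id", "spotid", "barcode", "id", "cell", "cell_id"}


def read_labels(path: str) -> "dict[str, str]":
    """Read a two-column (spot_id, label) CSV into an ordered mapping.

    A header row is auto-detected; labels are kept as opaque strings.
    Duplicate spot ids raise ValueError.
    """
    mapping: dict = {}
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if not rows:
        return mapping
    start = 0
    if rows[0] and rows[0][0].strip().lower() in _LABEL_HEADER_TOKENS:
        start = 1
    for row in rows[start:]:
        if len(row) < 2:
            raise FormatError(f"label row {row!r} does not have two columns")
        sid = row[0]
        if sid in mapping:
            raise ValueError(f"duplicate spot_id {sid!r} in labels file")
        mapping[sid] = row[1]
    return mapping


def write_labels(result, path: str, spot_ids: Optional[Sequence[str]] = None) -> None:
    """Write labels as a CSV (spot_id,label) that round-trips via read_labels.

    ``result`` may be a ClusterResult (refined labels are written), a
    mapping spot_id -> label, or a label sequence with explicit spot_ids.
    """
    if isinstance(result, Mapping):
        pairs = list(result.items())
    elif hasattr(result, "refined_labels"):
        labels = result.refined_labels
        ids = spot_ids if spot_ids is not None else getattr(result, "spot_ids", None)
        if ids is None:
            raise ValueError("spot_ids required to write a ClusterResult without ids")
        if len(ids) != len(labels):
            raise ValueError("one label per spot required")
        pairs = list(zip(ids, labels))
    else:
        if spot_ids is None:
            raise ValueError("spot_ids required when writing a raw label sequence")
        if len(spot_ids) != len(result):
            raise ValueError("one label per spot required")
        pairs = list(zip(spot_ids, result))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["spot_id", "label"])
        for sid, label in pairs:
            writer.writerow([sid, label])
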