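"""Gene filtration, HVG selection, normalization and spatial features.

The scatter filtration step iteratively samples random spots and removes
the genes that recur most often among each sampled spot's top-L expressed
genes — suppressing ubiquitously high "background" programs before
variance-based gene selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core_io import SpatialDataset

logger = logging.getLogger("stclust")


@dataclass
class FiltrationConfig:
    """Scatter-filtration hyperparameters.

    ``knob`` controls removal intensity: r = knob // 10 genes are removed
    per iteration. ``sample_size`` defaults to max(50, ceil(0.1 * n_spots))
    when left unset.
    """

    knob: int = 100
    n_iterations: int = 10
    sample_size: Optional[int] = None
    top_l: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.knob < 10:
            raise ValueError("knob must be >= 10 so that r = knob // 10 >= 1")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.top_l < 1:
            raise ValueError("top_l must be >= 1")

    @property
    def removal_per_iteration(self) -> int:
        return self.knob // 10

    def resolved_sample_size(self, n_spots: int) -> int:
        if self.sample_size is not None:
            if self.sample_size > n_spots:
                raise ValueError("sample_size exceeds number of spots")
            return self.sample_size
        return min(n_spots, max(50, math.ceil(0.1 * n_spots)))


@dataclass
class FiltrationResult:
    """Outcome of scatter filtration.

    retained_genes : ordered original gene indices that survived
    removed_per_iteration : list of per-iteration removed index lists
    occurrence_scores : per-iteration dict gene index -> occurrence count
    sampled_spots : per-iteration sampled spot index arrays
    """

    retained_genes: np.ndarray
    removed_per_iteration: list = field(default_factory=list)
    occurrence_scores: list = field(default_factory=list)
    sampled_spots: list = field(default_factory=list)


@dataclass
class NormalizationConfig:
    target_sum: float = 1e4
    clip_low: float = -10.0
    clip_high: float = 10.0
    global_center: bool = False

    def __post_init__(self):
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")
        if self.clip_low >= self.clip_high:
            raise ValueError("clip_low must be below clip_high")


@dataclass
class NeighborGraph:
    """Exact Euclidean k-nearest-neighbor graph (self excluded)."""

    k: int
    neighbor_indices: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        n = self.neighbor_indices.shape[0]
        if self.neighbor_indices.shape != (n, self.k):
            raise ValueError("neighbor_indices must be (n, k)")
        if np.any(self.neighbor_indices == np.arange(n)[:, None]):
            raise ValueError("a spot cannot be its own neighbor")

    @property
    def n_spots(self) -> int:
        return self.neighbor_indices.shape[0]


def build_knn_graph(coords: np.ndarray, k: int) -> NeighborGraph:
    """Exact Euclidean kNN over spatial coordinates, self excluded."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= k:
        raise ValueError(f"need more spots than neighbors (n={n}, k={k})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    neighbors = np.empty((n, k), dtype=int)
    distances = np.empty((n, k), dtype=float)
    for i in range(n):
        row = idx[i]
        keep = row != i
        # with duplicate coordinates the self index may not be returned first
        if keep.sum() == k + 1:
            keep[-1] = False
        neighbors[i] = row[keep][:k]
        distances[i] = dist[i][keep][:k]
    return NeighborGraph(k=k, neighbor_indices=neighbors, distances=distances)


def _top_l_indices(values: np.ndarray, l: int) -> np.ndarray:
    """Indices of the l largest values; ties broken by lower index."""
    order = np.argsort(-values, kind="stable")
    return order[:l]


def scatter_filtration(dataset, config: FiltrationConfig) -> FiltrationResult:
    """Iteratively remove genes recurring among top-L expressed genes.

    Per iteration: sample ``m`` spots without replacement, score every
    current gene by how many sampled spots list it among their top-L
    expressed genes, and remove the r = knob // 10 highest scorers.
    Score ties at the removal boundary are broken by higher total
    expression, then by gene index.
    """
    X = dataset.counts if isinstance(dataset, SpatialDataset) else np.asarray(dataset)
    n, p = X.shape
    T = config.n_iterations
    r = config.removal_per_iteration
    if T * r >= p - 1:
        raise ValueError(
            f"filtration would exhaust the gene set: {T} x {r} removals for {p} genes"
        )
    m = config.resolved_sample_size(n)
    rng = np.random.default_rng(config.seed)
    totals = np.asarray(X.sum(axis=0), dtype=float).ravel()

    current = np.arange(p)
    removed_sets, score_maps, samples = [], [], []
    for _ in range(T):
        sample = np.sort(rng.choice(n, size=m, replace=False))
        sub = np.asarray(X[np.ix_(sample, current)], dtype=float)
        L = min(config.top_l, current.size)
        counts = np.zeros(current.size, dtype=int)
        for row in sub:
            counts[_top_l_indices(row, L)] += 1
        order = sorted(
            range(current.size),
            key=lambda j: (-counts[j], -totals[current[j]], current[j]),
        )
        removed_local = np.array(sorted(order[:r]))
        removed = current[removed_local]
        removed_sets.append(removed)
        score_maps.append({int(g): int(c) for g, c in zip(current, counts)})
        samples.append(sample)
        current = np.delete(current, removed_local)
    return FiltrationResult(
        retained_genes=current,
        removed_per_iteration=removed_sets,
        occurrence_scores=score_maps,
        sampled_spots=samples,
    )


def select_hvg(counts: np.ndarray, n_top: int) -> np.ndarray:
    """Rank genes by variance-stabilized standardized variance.

    Fits a loess trend of log10 variance on log10 mean, standardizes the
    raw counts by the trend-predicted standard deviation with clipping at
    sqrt(n), and ranks genes by the variance of the clipped standardized
    values. Returns the top ``n_top`` gene indices in rank order.
    """
    X = np.asarray(counts, dtype=float)
    n, p = X.shape
    if n_top > p:
        raise ValueError("n_top exceeds gene count")
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n > 1 else np.zeros(p)
    if not np.any(var > 0):
        raise ValueError("all genes have zero variance")

    norm_var = np.zeros(p)
    usable = (mean > 0) & (var > 0)
    if usable.sum() >= 2:
        lx = np.log10(mean[usable])
        ly = np.log10(var[usable])
        # widen the span on small gene panels so single outliers cannot
        # drag the trend through themselves (robust iterations then
        # down-weight them)
        frac = max(0.3, min(1.0, 30.0 / usable.sum()))
        fitted = lowess(ly, lx, frac=frac, return_sorted=False)
        reg_std = np.sqrt(10.0**fitted)
        clip_val = mean[usable] + reg_std * np.sqrt(n)
        clipped = np.minimum(X[:, usable], clip_val[None, :])
        sq_sum = np.sum(clipped**2, axis=0)
        lin_sum = np.sum(clipped, axis=0)
        denom = (n - 1) * reg_std**2
        norm_var[usable] = (
            n * mean[usable] ** 2 + sq_sum - 2 * lin_sum * mean[usable]
        ) / denom
    else:  # degenerate input: fall back to the raw variance ranking
        norm_var[usable] = var[usable]
    order = sorted(range(p), key=lambda j: (-norm_var[j], j))
    return np.array(order[:n_top])


def normalize_expression(counts: np.ndarray, config: NormalizationConfig = None) -> np.ndarray:
    """Library-size scaling, log1p, per-gene z-score, then clipping.

    Zero-variance genes map to 0 after the z-score step. A spot with zero
    total count is an error (it cannot be library-size scaled).
    """
    if config is None:
        config = NormalizationConfig()
    X = np.asarray(counts, dtype=float)
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"spot(s) with zero total count: {zero[:5].tolist()}")
    X = X / totals[:, None] * config.target_sum
    X = np.log1p(X)
    if config.global_center:
        mu, sd = X.mean(), X.std()
        X = np.zeros_like(X) if sd == 0 else (X - mu) / sd
    else:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        out = np.zeros_like(X)
        nz = sd > 0
        out[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
        X = out
    return np.clip(X, config.clip_low, config.clip_high)


def neighborhood_features(X: np.ndarray, graph: NeighborGraph) -> np.ndarray:
    """Concatenate each spot's features with its neighborhood mean (n x 2p)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != graph.n_spots:
        raise ValueError("feature matrix and graph cover different spots")
    neigh_mean = X[graph.neighbor_indices].mean(axis=1)
    return np.hstack([X, neigh_mean])


def fuse_features(blocks, zscore: bool = False) -> np.ndarray:
    """Column-wise concatenation of feature blocks sharing the spot axis."""
    blocks = [np.asarray(b, dtype=float) for b in blocks]
    if not blocks:
        raise ValueError("no feature blocks given")
    n = blocks[0].shape[0]
    for b in blocks:
        if b.shape[0] != n:
            raise ValueError("feature blocks disagree on the number of spots")
    if zscore:
        fused = []
        for b in blocks:
            sd = b.std(axis=0)
            mu = b.mean(axis=0)
            z = np.zeros_like(b)
            nz = sd > 0
            z[:, nz] = (b[:, nz] - mu[nz]) / sd[nz]
            fused.append(z)
        blocks = fused
    return np.hstack(blocks)


def select_locations(dataset: SpatialDataset, keep_fraction: float) -> SpatialDataset:
    """Keep the top ceil(keep_fraction * n) spots ranked by total count.

    Total count is used as an informativeness proxy; original spot order
    is preserved among the retained spots.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    n = dataset.n_spots
    n_keep = math.ceil(keep_fraction * n)
    totals = np.asarray(dataset.counts.sum(axis=1), dtype=float).ravel()
    ranked = sorted(range(n), key=lambda i: (-totals[i], i))
    keep = np.sort(np.array(ranked[:n_keep]))
    return dataset.subset_spots(keep)
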