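"""Agreement metrics and unsupervised spatial cluster quality metrics.

Supervised: ARI, NMI, homogeneity, completeness — computed from the
contingency table with natural logarithms. Unsupervised: average
silhouette width, PAS (fraction of spots disagreeing with most of their
10 nearest spatial neighbors), CHAOS (z-scored within-cluster 1-NN edge
length), and Moran's I / Geary's C over per-cluster one-hot indicators
with row-normalized kNN weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Sequence, Tuple

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .preprocess import NeighborGraph

logger = logging.getLogger("stclust")


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_sums: np.ndarray
    col_sums: np.ndarray
    total: int


def _encode(labels) -> np.ndarray:
    labels = np.asarray(labels)
    _, enc = np.unique(labels, return_inverse=True)
    return enc


def contingency(labels_a, labels_b) -> ContingencyTable:
    """Exact co-occurrence counts between two labelings."""
    a = _encode(labels_a)
    b = _encode(labels_b)
    if len(a) != len(b):
        raise ValueError("labelings have different lengths")
    r, c = a.max() + 1, b.max() + 1
    counts = np.zeros((r, c), dtype=int)
    np.add.at(counts, (a, b), 1)
    return ContingencyTable(
        counts=counts,
        row_sums=counts.sum(axis=1),
        col_sums=counts.sum(axis=0),
        total=int(counts.sum()),
    )


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from the pair-counting contingency form."""
    table = contingency(labels_a, labels_b)
    n = table.total
    if n < 2:
        raise ValueError("ARI needs at least 2 samples")
    sum_ij = sum(comb(int(nij), 2) for nij in table.counts.ravel())
    sum_a = sum(comb(int(ai), 2) for ai in table.row_sums)
    sum_b = sum(comb(int(bj), 2) for bj in table.col_sums)
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both labelings trivially concordant
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(freq: np.ndarray) -> float:
    p = freq[freq > 0] / freq.sum()
    return float(-(p * np.log(p)).sum())


def nmi(labels_a, labels_b) -> float:
    """2 I(U;V) / (H(U) + H(V)) with natural logs; 1 for two zero-entropy labelings."""
    table = contingency(labels_a, labels_b)
    n = table.total
    if n < 2:
        raise ValueError("NMI needs at least 2 samples")
    hu = _entropy(table.row_sums.astype(float))
    hv = _entropy(table.col_sums.astype(float))
    if hu + hv == 0:
        return 1.0
    mi = 0.0
    for i, ai in enumerate(table.row_sums):
        for j, bj in enumerate(table.col_sums):
            nij = table.counts[i, j]
            if nij > 0:
                mi += (nij / n) * np.log(nij * n / (ai * bj))
    return float(2.0 * mi / (hu + hv))


def homogeneity_completeness(truth, pred) -> Tuple[float, float]:
    """Conditional-entropy homogeneity and completeness (degenerate cases -> 1)."""
    table = contingency(truth, pred)
    n = table.total
    ht = _entropy(table.row_sums.astype(float))
    hp = _entropy(table.col_sums.astype(float))
    # H(truth | pred)
    h_t_given_p = 0.0
    h_p_given_t = 0.0
    for i in range(table.counts.shape[0]):
        for j in range(table.counts.shape[1]):
            nij = table.counts[i, j]
            if nij > 0:
                h_t_given_p -= (nij / n) * np.log(nij / table.col_sums[j])
                h_p_given_t -= (nij / n) * np.log(nij / table.row_sums[i])
    homogeneity = 1.0 if ht == 0 else 1.0 - h_t_given_p / ht
    completeness = 1.0 if hp == 0 else 1.0 - h_p_given_t / hp
    return float(homogeneity), float(completeness)


def asw(features: np.ndarray, labels) -> float:
    """Mean silhouette (b - a) / max(a, b) with Euclidean distances."""
    labels = _encode(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return float(silhouette_score(np.asarray(features, dtype=float), labels))


def pas(labels, coords, n_neighbors: int = 10, threshold: int = 6) -> float:
    """Fraction of spots whose label differs from >= threshold of their
    n_neighbors nearest spatial neighbors."""
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    n = len(labels)
    if n <= n_neighbors:
        raise ValueError(f"PAS needs more than {n_neighbors} spots")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    abnormal = 0
    for i in range(n):
        neigh = idx[i][idx[i] != i][:n_neighbors]
        if np.sum(labels[neigh] != labels[i]) >= threshold:
            abnormal += 1
    return abnormal / n


def chaos(labels, coords) -> float:
    """Spot-count-weighted mean within-cluster 1-NN edge length on z-scored
    coordinates; lower values indicate spatially smoother domains."""
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    sd = coords.std(axis=0)
    mu = coords.mean(axis=0)
    z = np.zeros_like(coords)
    nz = sd > 0
    z[:, nz] = (coords[:, nz] - mu[nz]) / sd[nz]
    total, weight = 0.0, 0
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size < 2:
            logger.warning("CHAOS: singleton cluster %r excluded", lab)
            continue
        pts = z[members]
        nn = NearestNeighbors(n_neighbors=2).fit(pts)
        dist, _ = nn.kneighbors(pts)
        total += dist[:, 1].sum()
        weight += members.size
    if weight == 0:
        raise ValueError("CHAOS undefined: all clusters are singletons")
    return float(total / weight)


def spatial_autocorrelation(labels, graph: NeighborGraph) -> Tuple[float, float]:
    """Cluster-size-weighted Moran's I and Geary's C over one-hot indicators.

    Weights are the row-normalized kNN adjacency (w_ij = 1/k for each of
    spot i's k neighbors).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n != graph.n_spots:
        raise ValueError("labels and graph cover different spots")
    unique = np.unique(labels)
    if unique.size < 2:
        raise ValueError("spatial autocorrelation undefined for a constant labeling")
    k = graph.k
    w = 1.0 / k
    s0 = n  # each row of weights sums to 1
    morans, gearys, sizes = [], [], []
    for lab in unique:
        x = (labels == lab).astype(float)
        xc = x - x.mean()
        denom = np.sum(xc**2)
        if denom == 0:
            continue
        neigh = graph.neighbor_indices
        cross = np.sum(w * xc[:, None] * xc[neigh])
        sq = np.sum(w * (x[:, None] - x[neigh]) ** 2)
        morans.append((n / s0) * cross / denom)
        gearys.append(((n - 1) / (2 * s0)) * sq / denom)
        sizes.append(x.sum())
    sizes = np.asarray(sizes)
    return (
        float(np.average(morans, weights=sizes)),
        float(np.average(gearys, weights=sizes)),
    )


def pca_features(X: np.ndarray, n_components: int = 20, seed: int = 0) -> np.ndarray:
    """Shared low-dimensional feature space for cross-method comparisons."""
    X = np.asarray(X, dtype=float)
    n_components = min(n_components, min(X.shape) - 1)
    return PCA(n_components=n_components, random_state=seed).fit_transform(X)


def metric_report(
    pred,
    coords,
    features,
    graph: NeighborGraph,
    truth=None,
) -> dict:
    """Compute the full metric panel for one labeling."""
    report = {}
    if truth is not None:
        report["ARI"] = ari(truth, pred)
        report["NMI"] = nmi(truth, pred)
        hom, comp = homogeneity_completeness(truth, pred)
        report["homogeneity"] = hom
        report["completeness"] = comp
    report["ASW"] = asw(features, pred)
    report["PAS"] = pas(pred, coords)
    report["CHAOS"] = chaos(pred, coords)
    moran, geary = spatial_autocorrelation(pred, graph)
    report["MoranI"] = moran
    report["GearyC"] = geary
    return report
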