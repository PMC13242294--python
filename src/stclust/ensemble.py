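"""Unsupervised multi-metric ensemble selection.

Candidates are scored on five unsupervised metrics, min-max normalized
per metric across candidates, flipped to benefit form for lower-is-better
metrics, and the candidate whose normalized vector is Euclidean-closest
to a balanced reference profile (max ASW, max Moran's I, median PAS /
CHAOS / Geary's C) wins. Single-metric selectors are also provided.
Truth labels are never consulted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

from .core_io import SpatialDataset
from .preprocess import build_knn_graph, normalize_expression
from .quality_metrics import asw, chaos, pas, pca_features, spatial_autocorrelation

logger = logging.getLogger("stclust")

METRICS = ("ASW", "PAS", "CHAOS", "MoranI", "GearyC")
LOWER_BETTER = ("PAS", "CHAOS", "GearyC")
MAX_REFERENCE = ("ASW", "MoranI")


@dataclass
class MetricMatrix:
    methods: list
    raw: np.ndarray  # (n_methods, 5)
    normalized: np.ndarray  # (n_methods, 5), benefit form, in [0, 1]
    epsilon: float = 1e-8

    def column(self, metric: str, normalized: bool = True) -> np.ndarray:
        j = METRICS.index(metric)
        return (self.normalized if normalized else self.raw)[:, j]


@dataclass
class SelectionResult:
    reference: np.ndarray
    distances: Dict[str, float]
    selected: str
    rule: str
    matrix: MetricMatrix = None


def normalize_metric_matrix(
    raw: np.ndarray, methods: Sequence[str], epsilon: float = 1e-8
) -> MetricMatrix:
    """Per-metric min-max with epsilon in the denominator, then benefit flip."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != len(METRICS):
        raise ValueError(f"raw matrix must be (n_methods, {len(METRICS)})")
    if raw.shape[0] < 1:
        raise ValueError("at least one method required")
    bad = np.argwhere(~np.isfinite(raw))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"non-finite metric {METRICS[j]} for method {methods[i]!r}")
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    z = (raw - lo) / (hi - lo + epsilon)
    for metric in LOWER_BETTER:
        j = METRICS.index(metric)
        z[:, j] = 1.0 - z[:, j]
    return MetricMatrix(methods=list(methods), raw=raw, normalized=z, epsilon=epsilon)


def reference_profile(matrix: MetricMatrix) -> np.ndarray:
    """Max of normalized ASW and Moran's I; median of the remaining metrics."""
    ref = np.empty(len(METRICS))
    for j, metric in enumerate(METRICS):
        col = matrix.normalized[:, j]
        ref[j] = col.max() if metric in MAX_REFERENCE else float(np.median(col))
    return ref


def select_balanced(matrix: MetricMatrix) -> SelectionResult:
    """Argmin squared Euclidean distance to the balanced reference profile."""
    ref = reference_profile(matrix)
    distances = {
        m: float(np.sum((matrix.normalized[i] - ref) ** 2))
        for i, m in enumerate(matrix.methods)
    }
    best = min(sorted(distances), key=lambda m: distances[m])
    ties = [m for m, d in distances.items() if d == distances[best]]
    if len(ties) > 1:
        logger.warning("balanced selection tie among %s; choosing %r", ties, best)
    return SelectionResult(
        reference=ref, distances=distances, selected=best, rule="balanced", matrix=matrix
    )


def select_single_metric(matrix: MetricMatrix, metric: str) -> SelectionResult:
    """Extremal raw value in the metric's own direction (max ASW, min PAS/CHAOS)."""
    if metric not in ("ASW", "PAS", "CHAOS"):
        raise ValueError("single-metric rules support ASW, PAS and CHAOS")
    col = matrix.column(metric, normalized=False)
    sign = 1.0 if metric == "ASW" else -1.0
    scores = {m: float(sign * col[i]) for i, m in enumerate(matrix.methods)}
    best = max(sorted(scores), key=lambda m: scores[m])
    ties = [m for m, s in scores.items() if s == scores[best]]
    if len(ties) > 1:
        logger.warning("%s selection tie among %s; choosing %r", metric, ties, best)
    distances = {m: -s for m, s in scores.items()}
    ref = reference_profile(matrix)
    return SelectionResult(
        reference=ref, distances=distances, selected=best, rule=metric.lower(), matrix=matrix
    )


def _as_label_array(candidate, spot_ids) -> np.ndarray:
    if isinstance(candidate, Mapping):
        missing = [s for s in spot_ids if s not in candidate]
        if missing:
            raise ValueError(f"candidate labeling missing {len(missing)} spots")
        return np.asarray([candidate[s] for s in spot_ids])
    arr = np.asarray(candidate)
    if len(arr) != len(spot_ids):
        raise ValueError("candidate labeling does not cover every spot")
    return arr


def run_ensemble(
    dataset: SpatialDataset,
    candidate_labelings: Mapping[str, object],
    rule: str = "balanced",
    k_neighbors: int = 6,
    n_pcs: int = 20,
    epsilon: float = 1e-8,
) -> Tuple[SelectionResult, np.ndarray]:
    """Score candidates on shared features, apply a selection rule.

    ASW is computed on a shared PCA representation of the normalized
    expression matrix so external candidates are scored on identical
    features. Truth labels are never read.
    """
    if not candidate_labelings:
        raise ValueError("no candidate labelings given")
    names = sorted(candidate_labelings)
    labels = {m: _as_label_array(candidate_labelings[m], dataset.spot_ids) for m in names}
    features = pca_features(normalize_expression(dataset.counts), n_components=n_pcs)
    graph = build_knn_graph(dataset.coords, k_neighbors)
    raw = np.empty((len(names), len(METRICS)))
    for i, m in enumerate(names):
        lab = labels[m]
        moran, geary = spatial_autocorrelation(lab, graph)
        raw[i] = [
            asw(features, lab),
            pas(lab, dataset.coords),
            chaos(lab, dataset.coords),
            moran,
            geary,
        ]
    matrix = normalize_metric_matrix(raw, names, epsilon=epsilon)
    if rule == "balanced":
        selection = select_balanced(matrix)
    elif rule.lower() in ("asw", "pas", "chaos"):
        selection = select_single_metric(matrix, rule.upper())
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return selection, labels[selection.selected]
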