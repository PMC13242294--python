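"""Gaussian-mixture labeling, spatial refinement and variant orchestration.

The final labeler is an EM-fitted Gaussian mixture over the latent
embedding (a shared full covariance by default — the closest simple
analogue of an equal-covariance model family). EM is implemented here
rather than delegated so the per-iteration log-likelihood trace is part
of the contract (it must be non-decreasing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .core_io import RunConfig, SpatialDataset
from .preprocess import (
    NeighborGraph,
    build_knn_graph,
    fuse_features,
    neighborhood_features,
    normalize_expression,
    scatter_filtration,
    select_hvg,
)
from .representation import (
    init_model,
    soft_assign,
    train_stage1_reconstruction,
    train_stage2_cluster_alignment,
    train_stage3_joint,
)

logger = logging.getLogger("stclust")

COVARIANCE_MODELS = ("shared_full", "full", "diagonal")


@dataclass
class GMMConfig:
    covariance_model: str = "shared_full"
    max_iter: int = 300
    tol: float = 1e-6
    reg: float = 1e-6
    n_init: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.covariance_model not in COVARIANCE_MODELS:
            raise ValueError(f"covariance_model must be one of {COVARIANCE_MODELS}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.reg < 0:
            raise ValueError("reg must be non-negative")


@dataclass
class ClusterResult:
    labels: np.ndarray
    refined_labels: np.ndarray
    responsibilities: np.ndarray
    n_effective_clusters: int
    variant: str = ""
    provenance: dict = field(default_factory=dict)
    log_likelihood_history: list = field(default_factory=list)
    spot_ids: Optional[list] = None

    def __post_init__(self):
        if len(self.labels) != len(self.refined_labels):
            raise ValueError("labels/refined_labels length mismatch")
        if self.responsibilities.shape[0] != len(self.labels):
            raise ValueError("responsibilities rows must match spot count")
        rowsum = self.responsibilities.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-6):
            raise ValueError("responsibility rows must sum to 1")


def _log_gauss(Z, means, covs, model):
    """Per-component Gaussian log densities, (n, K)."""
    n, d = Z.shape
    K = means.shape[0]
    out = np.empty((n, K))
    if model == "diagonal":
        for k in range(K):
            var = covs[k]
            diff = Z - means[k]
            out[:, k] = -0.5 * (
                d * np.log(2 * np.pi) + np.sum(np.log(var)) + np.sum(diff**2 / var, axis=1)
            )
        return out
    for k in range(K):
        cov = covs if model == "shared_full" else covs[k]
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular covariance despite regularization; increase GMMConfig.reg"
            ) from exc
        diff = Z - means[k]
        y = solve_triangular(chol, diff.T, lower=True).T
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(y**2, axis=1))
    return out


def _m_step(Z, resp, reg, model):
    n, d = Z.shape
    K = resp.shape[1]
    nk = resp.sum(axis=0) + 10 * np.finfo(float).eps
    weights = nk / n
    means = (resp.T @ Z) / nk[:, None]
    if model == "diagonal":
        covs = np.empty((K, d))
        for k in range(K):
            diff = Z - means[k]
            covs[k] = (resp[:, k] @ diff**2) / nk[k] + reg
    elif model == "full":
        covs = np.empty((K, d, d))
        for k in range(K):
            diff = Z - means[k]
            covs[k] = (diff.T * resp[:, k]) @ diff / nk[k] + reg * np.eye(d)
    else:  # shared_full
        covs = np.zeros((d, d))
        for k in range(K):
            diff = Z - means[k]
            covs += (diff.T * resp[:, k]) @ diff
        covs = covs / n + reg * np.eye(d)
    return weights, means, covs


def _em_once(Z, K, cfg: GMMConfig, init_seed: int):
    n, d = Z.shape
    km = KMeans(n_clusters=K, n_init=1, random_state=init_seed).fit(Z)
    resp = np.zeros((n, K))
    resp[np.arange(n), km.labels_] = 1.0
    weights, means, covs = _m_step(Z, resp, cfg.reg, cfg.covariance_model)
    history = []
    prev = -np.inf
    for _ in range(cfg.max_iter):
        log_prob = _log_gauss(Z, means, covs, cfg.covariance_model) + np.log(
            np.maximum(weights, 1e-300)
        )
        log_norm = logsumexp(log_prob, axis=1)
        ll = float(log_norm.mean())
        history.append(ll)
        resp = np.exp(log_prob - log_norm[:, None])
        if ll - prev < cfg.tol and np.isfinite(prev):
            break
        prev = ll
        weights, means, covs = _m_step(Z, resp, cfg.reg, cfg.covariance_model)
    return ll, resp, history


def gmm_fit(Z: np.ndarray, K: int, cfg: GMMConfig = None) -> ClusterResult:
    """EM-fitted Gaussian mixture; best of n_init runs by log-likelihood.

    Initialization is k-means-style; labels are the argmax responsibility.
    Empty components are reported through n_effective_clusters, never
    silently re-fit.
    """
    if cfg is None:
        cfg = GMMConfig()
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n <= K:
        raise ValueError(f"need more points than components (n={n}, K={K})")
    if K == 1:
        resp = np.ones((n, 1))
        return ClusterResult(
            labels=np.zeros(n, dtype=int),
            refined_labels=np.zeros(n, dtype=int),
            responsibilities=resp,
            n_effective_clusters=1,
        )
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_init)
    best = None
    for s in seeds:
        ll, resp, history = _em_once(Z, K, cfg, int(s % (2**31 - 1)))
        if best is None or ll > best[0]:
            best = (ll, resp, history)
    _, resp, history = best
    labels = resp.argmax(axis=1)
    return ClusterResult(
        labels=labels,
        refined_labels=labels.copy(),
        responsibilities=resp,
        n_effective_clusters=int(len(np.unique(labels))),
        log_likelihood_history=history,
    )


def refine_labels(
    labels: np.ndarray,
    graph: NeighborGraph,
    iterate: bool = False,
    max_passes: int = 10,
) -> np.ndarray:
    """Strict-majority neighbor vote relabeling (synchronous).

    A spot flips to label l iff l differs from its current label and
    strictly more than k/2 of its spatial neighbors carry l. Ties and
    absent majorities leave the spot unchanged.
    """
    labels = np.asarray(labels)
    if len(labels) != graph.n_spots:
        raise ValueError("labels and graph cover different spots")
    k = graph.k
    current = labels.copy()
    passes = max_passes if iterate else 1
    for _ in range(passes):
        neigh = current[graph.neighbor_indices]
        updated = current.copy()
        for i in range(len(current)):
            vals, counts = np.unique(neigh[i], return_counts=True)
            j = counts.argmax()
            if counts[j] * 2 > k and vals[j] != current[i]:
                updated[i] = vals[j]
        if np.array_equal(updated, current):
            break
        current = updated
    return current


def one_hot_targets(labels: np.ndarray, K: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min(initial=0) < 0 or (labels.size and labels.max() >= K):
        raise ValueError(f"labels must lie in [0, {K})")
    Y = np.zeros((len(labels), K))
    Y[np.arange(len(labels)), labels] = 1.0
    return Y


def _prepare_features(dataset: SpatialDataset, config: RunConfig):
    """Filtration / HVG / normalization / variant-specific feature fusion."""
    from .preprocess import FiltrationConfig

    provenance = {}
    work = dataset
    if config.variant in ("Scatter", "FACT"):
        filt_cfg = config.filtration
        if not isinstance(filt_cfg, FiltrationConfig):
            filt_cfg = FiltrationConfig(**(filt_cfg or {}))
        filt = scatter_filtration(work, filt_cfg)
        work = work.subset_genes(filt.retained_genes)
        provenance["retained_genes"] = [work.gene_ids[i] for i in range(work.n_genes)]
        provenance["n_removed_by_filtration"] = int(
            dataset.n_genes - len(filt.retained_genes)
        )
    n_top = min(config.n_hvg, work.n_genes)
    hvg = select_hvg(work.counts, n_top)
    work = work.subset_genes(np.sort(hvg))
    provenance["n_hvg"] = int(n_top)
    X = normalize_expression(work.counts, config.normalization)
    if config.variant == "GS":
        X = fuse_features([X, work.coords], zscore=True)
    elif config.variant == "GN":
        graph = build_knn_graph(work.coords, config.k_neighbors)
        X = neighborhood_features(X, graph)
    return X, work, provenance


def run_variant(dataset: SpatialDataset, config: RunConfig) -> ClusterResult:
    """Execute a full variant pipeline and return refined cluster labels.

    G       HVG -> normalize -> AE stage 1 -> GMM
    GS      as G with z-scored coordinates fused into the input
    GN      as G with neighborhood-mean features concatenated
    Scatter scatter filtration -> HVG -> normalize -> AE stage 1 -> GMM
    ACT     G pipeline, then staged clustering-layer training against
            spatially refined GMM targets and a final GMM on the latent
    FACT    ACT preceded by scatter filtration

    Every variant ends with spatial strict-majority refinement.
    """
    try:
        X, work, provenance = _prepare_features(dataset, config)
    except Exception as exc:
        raise type(exc)(f"[feature preparation] {exc}") from exc
    K = config.n_clusters
    graph = build_knn_graph(work.coords, config.k_neighbors)
    seed_model = int(config.substream("init_model").integers(2**31 - 1))
    seed_gmm = int(config.substream("gmm").integers(2**31 - 1))
    gmm_cfg = config.gmm
    model = init_model(X.shape[1], config.latent_dim, K, seed=seed_model)

    try:
        model = train_stage1_reconstruction(model, X, config.training)
        Z = X @ model.W1
        if config.variant in ("ACT", "FACT"):
            import dataclasses

            stage_gmm = dataclasses.replace(gmm_cfg, seed=seed_gmm)
            interim = gmm_fit(Z, K, stage_gmm)
            targets = refine_labels(interim.labels, graph)
            Y = one_hot_targets(targets, K)
            model = train_stage2_cluster_alignment(model, X, Y, config.training)
            stage_gmm2 = dataclasses.replace(gmm_cfg, seed=seed_gmm + 1)
            interim2 = gmm_fit(X @ model.W1, K, stage_gmm2)
            targets2 = refine_labels(interim2.labels, graph)
            Y2 = one_hot_targets(targets2, K)
            model = train_stage3_joint(model, X, Y2, config.training)
            Z = X @ model.W1
        import dataclasses

        final_gmm = dataclasses.replace(gmm_cfg, seed=seed_gmm + 2)
        result = gmm_fit(Z, K, final_gmm)
    except Exception as exc:
        raise type(exc)(f"[{config.variant} pipeline] {exc}") from exc

    refined = refine_labels(result.labels, graph)
    provenance.update(
        {
            "variant": config.variant,
            "seed": config.seed,
            "n_clusters": K,
            "latent_dim": config.latent_dim,
            "k_neighbors": config.k_neighbors,
        }
    )
    return ClusterResult(
        labels=result.labels,
        refined_labels=refined,
        responsibilities=result.responsibilities,
        n_effective_clusters=result.n_effective_clusters,
        variant=config.variant,
        provenance=provenance,
        log_likelihood_history=result.log_likelihood_history,
        spot_ids=list(work.spot_ids),
    )
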