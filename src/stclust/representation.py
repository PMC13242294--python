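"""Linear autoencoder with a softmax clustering head, trained in stages.

The model is three weight matrices: encoder W1 (d_in x d_latent), decoder
W2 (d_latent x d_in) and clustering layer W3 (d_latent x K). Maps are
purely linear with no bias, as specified. Training is full-batch adaptive
moment gradient descent:

  stage 1  reconstruction only (W1, W2)
  stage 2  clustering-layer alignment to one-hot targets (W3 only; W1, W2
           frozen)
  stage 3  joint fine-tuning of all weights on
           lambda_rec * L_rec + lambda_clust * L_clust

L_clust is the mean over spots of the row-wise KL divergence from the
target distribution to the softmax assignments, making the weighting
independent of the number of spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

EPS_Q = 1e-10


@dataclass
class TrainingConfig:
    lambda_rec: float = 1.0
    lambda_clust: float = 0.1
    epochs_stage1: int = 200
    epochs_stage2: int = 100
    epochs_stage3: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.lambda_rec < 0 or self.lambda_clust < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lambda_rec + self.lambda_clust == 0:
            raise ValueError("lambda_rec + lambda_clust must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class LatentModel:
    W1: np.ndarray
    W2: np.ndarray
    W3: np.ndarray
    d_in: int
    d_latent: int
    K: int
    loss_history: list = field(default_factory=list)

    def __post_init__(self):
        if self.W1.shape != (self.d_in, self.d_latent):
            raise ValueError("W1 shape mismatch")
        if self.W2.shape != (self.d_latent, self.d_in):
            raise ValueError("W2 shape mismatch")
        if self.W3.shape != (self.d_latent, self.K):
            raise ValueError("W3 shape mismatch")


@dataclass
class SoftAssignment:
    """Row-stochastic soft cluster assignments with raw scores."""

    Q: np.ndarray
    raw_scores: np.ndarray


def init_model(d_in: int, d_latent: int = 32, K: int = 7, seed: int = 0) -> LatentModel:
    """Randomly initialized model; deterministic under seed, never pretrained."""
    if min(d_in, d_latent, K) < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, d_latent))
    W2 = rng.normal(0.0, 1.0 / np.sqrt(d_latent), size=(d_latent, d_in))
    W3 = rng.normal(0.0, 1.0 / np.sqrt(d_latent), size=(d_latent, K))
    return LatentModel(W1=W1, W2=W2, W3=W3, d_in=d_in, d_latent=d_latent, K=K)


def encode(X: np.ndarray, model: LatentModel) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.d_in:
        raise ValueError(f"X has width {X.shape[1]}, model expects {model.d_in}")
    return X @ model.W1


def reconstruct(Z: np.ndarray, model: LatentModel) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != model.d_latent:
        raise ValueError("latent width mismatch")
    return Z @ model.W2


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Mean over spots of the squared Euclidean row distance."""
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.sum((X - X_hat) ** 2, axis=1)))


def soft_assign(Z: np.ndarray, model: LatentModel) -> SoftAssignment:
    """Row-wise softmax of Z W3, stabilized by row-max subtraction."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != model.d_latent:
        raise ValueError("latent width mismatch")
    S = Z @ model.W3
    shifted = S - S.max(axis=1, keepdims=True)
    expS = np.exp(shifted)
    Q = expS / expS.sum(axis=1, keepdims=True)
    return SoftAssignment(Q=Q, raw_scores=S)


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Mean over rows of sum_k P log(P / Q); zero P entries contribute 0."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("shape mismatch")
    if np.any(P < 0) or np.any(Q < 0):
        raise ValueError("distributions must be non-negative")
    Qf = np.maximum(Q, EPS_Q)
    terms = np.where(P > 0, P * (np.log(np.maximum(P, EPS_Q)) - np.log(Qf)), 0.0)
    return float(terms.sum(axis=1).mean())


class _Adam:
    """Adaptive-moment gradient descent over a list of parameter arrays."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _check_finite(loss: float, epoch: int, stage: str) -> None:
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite loss at {stage} epoch {epoch}")


def train_stage1_reconstruction(
    model: LatentModel, X: np.ndarray, cfg: TrainingConfig
) -> LatentModel:
    """Gradient descent on the reconstruction loss only (W1 and W2)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    opt = _Adam([model.W1, model.W2], cfg.learning_rate)
    for epoch in range(cfg.epochs_stage1):
        Z = X @ model.W1
        E = Z @ model.W2 - X
        loss = float(np.mean(np.sum(E**2, axis=1)))
        _check_finite(loss, epoch, "stage1")
        gW2 = (2.0 / n) * Z.T @ E
        gW1 = (2.0 / n) * X.T @ (E @ model.W2.T)
        opt.step([gW1, gW2])
        model.loss_history.append(
            {"stage": 1, "epoch": epoch, "L_rec": loss, "L_clust": 0.0, "L_total": loss}
        )
    return model


def train_stage2_cluster_alignment(
    model: LatentModel, X: np.ndarray, Y_targets: np.ndarray, cfg: TrainingConfig
) -> LatentModel:
    """Train only the clustering layer against one-hot targets (W1, W2 frozen)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y_targets, dtype=float)
    if Y.shape[1] != model.K:
        raise ValueError(f"targets have {Y.shape[1]} clusters, model has {model.K}")
    n = X.shape[0]
    Z = X @ model.W1  # frozen throughout the stage
    opt = _Adam([model.W3], cfg.learning_rate)
    for epoch in range(cfg.epochs_stage2):
        Q = soft_assign(Z, model).Q
        loss = kl_divergence(Y, Q)
        _check_finite(loss, epoch, "stage2")
        gS = (Q - Y) / n
        gW3 = Z.T @ gS
        opt.step([gW3])
        model.loss_history.append(
            {"stage": 2, "epoch": epoch, "L_rec": 0.0, "L_clust": loss, "L_total": loss}
        )
    return model


def train_stage3_joint(
    model: LatentModel, X: np.ndarray, Y_targets: np.ndarray, cfg: TrainingConfig
) -> LatentModel:
    """Unfreeze everything; minimize lambda_rec * L_rec + lambda_clust * L_clust."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y_targets, dtype=float)
    if Y.shape[1] != model.K:
        raise ValueError("target cluster count mismatch")
    n = X.shape[0]
    opt = _Adam([model.W1, model.W2, model.W3], cfg.learning_rate)
    for epoch in range(cfg.epochs_stage3):
        Z = X @ model.W1
        E = Z @ model.W2 - X
        l_rec = float(np.mean(np.sum(E**2, axis=1)))
        Q = soft_assign(Z, model).Q
        l_clust = kl_divergence(Y, Q)
        loss = cfg.lambda_rec * l_rec + cfg.lambda_clust * l_clust
        _check_finite(loss, epoch, "stage3")
        gW2 = cfg.lambda_rec * (2.0 / n) * Z.T @ E
        gZ = cfg.lambda_rec * (2.0 / n) * E @ model.W2.T
        gS = cfg.lambda_clust * (Q - Y) / n
        gW3 = Z.T @ gS
        gZ = gZ + gS @ model.W3.T
        gW1 = X.T @ gZ
        opt.step([gW1, gW2, gW3])
        model.loss_history.append(
            {"stage": 3, "epoch": epoch, "L_rec": l_rec, "L_clust": l_clust, "L_total": loss}
        )
    return model


def hill_climb_train(
    model: LatentModel,
    X: np.ndarray,
    cfg: TrainingConfig,
    n_iterations: int = 50,
    eps: float = 0.5,
    min_samples: int = 5,
    noise_scale: float = 0.01,
) -> LatentModel:
    """Ablation-only metaheuristic trainer.

    Perturbs one weight tensor per step (round-robin, additive Gaussian
    noise) and accepts the perturbation iff the average silhouette width
    of a density-based clustering of the latent embedding strictly
    improves. Degenerate clusterings (fewer than 2 clusters) score -1.
    """
    from sklearn.cluster import DBSCAN
    from sklearn.metrics import silhouette_score

    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(cfg.seed)

    def fitness(m: LatentModel) -> float:
        Z = X @ m.W1
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(Z)
        if len(set(labels)) < 2:
            return -1.0
        return float(silhouette_score(Z, labels))

    best = fitness(model)
    tensors = ["W1", "W2", "W3"]
    for it in range(n_iterations):
        name = tensors[it % 3]
        W = getattr(model, name)
        noise = rng.normal(0.0, noise_scale, size=W.shape)
        W += noise
        trial = fitness(model)
        if trial > best:
            best = trial
        else:
            W -= noise
        model.loss_history.append({"stage": "hill", "iteration": it, "fitness": best})
    return model


def save_model(model: LatentModel, path: str) -> None:
    """Persist weights and loss history to an HDF5 container."""
    import json

    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("W1", data=model.W1)
        fh.create_dataset("W2", data=model.W2)
        fh.create_dataset("W3", data=model.W3)
        fh.attrs["d_in"] = model.d_in
        fh.attrs["d_latent"] = model.d_latent
        fh.attrs["K"] = model.K
        fh.attrs["loss_history"] = json.dumps(model.loss_history)


def load_model(path: str) -> LatentModel:
    import json

    import h5py

    with h5py.File(path, "r") as fh:
        model = LatentModel(
            W1=fh["W1"][...],
            W2=fh["W2"][...],
            W3=fh["W3"][...],
            d_in=int(fh.attrs["d_in"]),
            d_latent=int(fh.attrs["d_latent"]),
            K=int(fh.attrs["K"]),
            loss_history=json.loads(fh.attrs["loss_history"]),
        )
    return model
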