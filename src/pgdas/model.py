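"""Dual-autoencoder deep clustering on a population graph.

Two encoders learn complementary views of a cohort: a dense autoencoder (AE)
compresses each subject's FC feature vector, while a graph autoencoder (GAE)
propagates features along the population graph with the normalized operator
A_hat and reconstructs the adjacency from embedding inner products. The two
embeddings are adaptively fused through a learnable per-dimension sigmoid
gate, refined by single-head sample-level self-attention with a residual
connection, and clustered with k-means++. Training alternates gradient
steps on a joint loss

    L = MSE(X, X_hat) + beta * BCE(binarized W, sigmoid(Z Z^T))
        + gamma * KL(P || Q)

with periodic refreshes of the self-supervised target distribution P, a
sharpened (squared, frequency-normalized) version of the Student-t soft
assignment Q. Early stopping fires when the hard labels stop changing
between consecutive target refreshes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .autodiff import AdamW, Tensor
from .popgraph import PopulationGraph

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "ClusterState",
    "PGDASModel",
    "soft_assign",
    "target_distribution",
    "kl_divergence",
    "total_loss",
    "init_centroids",
    "fit",
    "select_k",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow common deep-embedded-clustering practice: a small latent
    dimension, L2 weight decay 1e-4, dropout 0.2 in the AE hidden layers,
    Student-t kernel with one degree of freedom, and a target-distribution
    refresh every 5 epochs with early stopping once fewer than 0.1% of hard
    labels change between refreshes.
    """

    k: int = 2
    embed_dim: int = 32
    ae_hidden: tuple[int, int] = (512, 256)
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    dropout: float = 0.2
    pretrain_epochs: int = 50
    max_epochs: int = 200
    target_update_interval: int = 5
    stop_tol: float = 0.001
    beta: float = 1.0
    gamma: float = 0.1
    alpha: float = 1.0
    leaky_slope: float = 0.01
    use_fusion: bool = True
    use_attention: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if min(self.beta, self.gamma, self.weight_decay) < 0:
            raise ValueError("loss weights and weight decay must be non-negative")
        if self.alpha <= 0:
            raise ValueError("alpha (t-kernel degrees of freedom) must be positive")


@dataclass
class ClusterState:
    """Everything the fit produces: embeddings, centroids, assignments, history."""

    Z_AE: np.ndarray
    Z_GAE: np.ndarray
    Z_fused: np.ndarray
    Z_refined: np.ndarray
    centroids: np.ndarray
    Q: np.ndarray
    P: np.ndarray
    labels: np.ndarray
    history: list[dict] = field(default_factory=list)
    config: TrainConfig | None = None


# --------------------------------------------------------------- assignments

def soft_assign(Z: np.ndarray, mu: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Student-t soft assignment: q_ij ∝ (1 + ||z_i - mu_j||^2 / alpha)^-(alpha+1)/2."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    Z = np.asarray(Z, float)
    mu = np.asarray(mu, float)
    d2 = ((Z[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    base = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return base / base.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened self-supervision target: p_ij ∝ q_ij^2 / f_j with f_j = Σ_i q_ij."""
    Q = np.asarray(Q, float)
    f = Q.sum(axis=0)
    if np.any(f <= 0):
        raise ValueError("empty cluster")
    W = Q**2 / f
    return W / W.sum(axis=1, keepdims=True)


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Mean-per-subject KL(P||Q) for row-stochastic P, Q."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    mask = P > 0
    return float(np.sum(P[mask] * (np.log(P[mask]) - np.log(Q[mask]))) / P.shape[0])


def _bce_weighted(targets: np.ndarray, probs: np.ndarray, pos_weight: float) -> float:
    eps = 1e-12
    p = np.clip(probs, eps, 1 - eps)
    loss = -(pos_weight * targets * np.log(p) + (1 - targets) * np.log(1 - p))
    return float(loss.mean())


def total_loss(features: np.ndarray, recon_features: np.ndarray,
               W: np.ndarray, W_hat: np.ndarray,
               Q: np.ndarray, P: np.ndarray,
               beta: float = 1.0, gamma: float = 0.1) -> float:
    """Reference (pure numpy) joint loss: MSE + beta*weighted BCE + gamma*KL."""
    mse = float(np.mean((np.asarray(features) - np.asarray(recon_features)) ** 2))
    targets = (np.asarray(W) > 0).astype(float)
    n_ones = targets.sum()
    n_zeros = targets.size - n_ones
    pos_weight = (n_zeros / n_ones) if n_ones > 0 else 1.0
    bce = _bce_weighted(targets, np.asarray(W_hat), pos_weight)
    return mse + beta * bce + gamma * kl_divergence(P, Q)


def init_centroids(Z: np.ndarray, K: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """k-means++ seeding plus Lloyd iterations to convergence.

    Returns (centroids, hard labels); deterministic given the seed.
    """
    Z = np.asarray(Z, float)
    n_distinct = np.unique(Z, axis=0).shape[0]
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the {n_distinct} distinct embedding rows")
    km = KMeans(n_clusters=K, init="k-means++", n_init=1, tol=1e-6,
                max_iter=300, random_state=seed % (2**31))
    labels = km.fit_predict(Z)
    return km.cluster_centers_.copy(), labels


# -------------------------------------------------------------------- model

def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


class PGDASModel:
    """Parameter container and forward passes for the dual autoencoders.

    All parameters are initialized from one generator so that a single
    integer seed fixes the whole run; dropout masks are drawn from the same
    generator during training and disabled at inference.
    """

    def __init__(self, n_features: int, config: TrainConfig,
                 rng: np.random.Generator):
        self.config = config
        F = n_features
        d = config.embed_dim
        hidden = tuple(min(h, F) for h in config.ae_hidden)
        if hidden != tuple(config.ae_hidden):
            logger.warning("AE hidden widths %s shrunk to %s to fit F=%d",
                           config.ae_hidden, hidden, F)
        self.widths = (F, *hidden, d)

        def lin(fi, fo):
            return (Tensor(_he_init(rng, fi, fo), requires_grad=True),
                    Tensor(np.zeros(fo), requires_grad=True))

        enc_dims = list(zip(self.widths[:-1], self.widths[1:]))
        dec_dims = [(b, a) for a, b in reversed(enc_dims)]
        self.ae_enc = [lin(a, b) for a, b in enc_dims]
        self.ae_dec = [lin(a, b) for a, b in dec_dims]
        self.gae = [lin(a, b) for a, b in enc_dims]
        self.gate = Tensor(np.zeros(d), requires_grad=True)
        scale = 1.0 / np.sqrt(d)
        self.attn_q = Tensor(rng.normal(0, scale, (d, d)), requires_grad=True)
        self.attn_k = Tensor(rng.normal(0, scale, (d, d)), requires_grad=True)
        self.attn_v = Tensor(np.zeros((d, d)), requires_grad=True)
        self.centroids: Tensor | None = None
        self._rng = rng

    # parameter bookkeeping -------------------------------------------------
    def parameters(self, include_centroids: bool = False):
        params, decay = [], []
        for W, b in (*self.ae_enc, *self.ae_dec, *self.gae):
            params += [W, b]
            decay += [True, False]
        params += [self.gate, self.attn_q, self.attn_k, self.attn_v]
        decay += [False, True, True, True]
        if include_centroids and self.centroids is not None:
            params.append(self.centroids)
            decay.append(False)
        return params, decay

    # forward passes --------------------------------------------------------
    def _dropout(self, h: Tensor, training: bool) -> Tensor:
        p = self.config.dropout
        if not training or p == 0:
            return h
        mask = (self._rng.random(h.shape) >= p) / (1.0 - p)
        return h * Tensor(mask)

    def ae_forward(self, X: Tensor, training: bool = False) -> tuple[Tensor, Tensor]:
        """Dense autoencoder: LeakyReLU after all but the final encoder and
        decoder layers, dropout in the hidden layers while training."""
        slope = self.config.leaky_slope
        h = X
        for i, (W, b) in enumerate(self.ae_enc):
            h = h @ W + b
            if i < len(self.ae_enc) - 1:
                h = self._dropout(h.leaky_relu(slope), training)
        z = h
        h = z
        for i, (W, b) in enumerate(self.ae_dec):
            h = h @ W + b
            if i < len(self.ae_dec) - 1:
                h = self._dropout(h.leaky_relu(slope), training)
        return z, h

    def gae_forward(self, X: Tensor, A_hat: Tensor,
                    training: bool = False) -> tuple[Tensor, Tensor]:
        """Graph autoencoder: three propagation layers H <- act(A_hat H W),
        linear last; decoder reconstructs the adjacency as sigmoid(Z Z^T)."""
        if A_hat.shape[0] != A_hat.shape[1] or A_hat.shape[0] != X.shape[0]:
            raise ValueError("A_hat must be S x S and aligned with the features")
        slope = self.config.leaky_slope
        h = X
        for i, (W, b) in enumerate(self.gae):
            h = A_hat @ (h @ W) + b
            if i < len(self.gae) - 1:
                h = h.leaky_relu(slope)
        z = h
        w_hat = (z @ z.T).sigmoid()
        return z, w_hat

    def fuse(self, Z_GAE: Tensor, Z_AE: Tensor) -> Tensor:
        """Adaptive per-dimension gate: Zi = g ⊙ Z_GAE + (1-g) ⊙ Z_AE."""
        if Z_GAE.shape != Z_AE.shape:
            raise ValueError("embeddings to fuse must have identical shapes")
        if not self.config.use_fusion:
            return Z_AE
        g = self.gate.sigmoid()
        return g * Z_GAE + (1.0 - g) * Z_AE

    def attention_refine(self, Zi: Tensor) -> Tensor:
        """Single-head sample-level self-attention with a residual connection."""
        if not self.config.use_attention:
            return Zi
        d = self.config.embed_dim
        scores = (Zi @ self.attn_q) @ (Zi @ self.attn_k).T / np.sqrt(d)
        A = scores.softmax_rows()
        return Zi + A @ (Zi @ self.attn_v)

    def embed(self, X: Tensor, A_hat: Tensor,
              training: bool = False) -> dict[str, Tensor]:
        z_ae, x_hat = self.ae_forward(X, training)
        z_gae, w_hat = self.gae_forward(X, A_hat, training)
        zi = self.fuse(z_gae, z_ae)
        z_ref = self.attention_refine(zi)
        return {"Z_AE": z_ae, "X_hat": x_hat, "Z_GAE": z_gae,
                "W_hat": w_hat, "Z_fused": zi, "Z_refined": z_ref}

    def soft_assign_t(self, Z: Tensor) -> Tensor:
        """Differentiable Student-t soft assignment against the centroids."""
        mu = self.centroids
        alpha = self.config.alpha
        d2 = ((Z * Z).sum(axis=1, keepdims=True)
              + (mu * mu).sum(axis=1)
              - 2.0 * (Z @ mu.T))
        base = (1.0 + d2 * (1.0 / alpha)).pow(-(alpha + 1.0) / 2.0)
        return base / base.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------- training

def _loss_terms(model: PGDASModel, X: Tensor, A_hat: Tensor,
                targets: Tensor, pos_weight: float, training: bool,
                P: np.ndarray | None) -> tuple[Tensor, dict[str, float]]:
    out = model.embed(X, A_hat, training=training)
    cfg = model.config
    diff = X - out["X_hat"]
    mse = (diff * diff).mean()

    eps = 1e-7
    p_hat = out["W_hat"] * (1 - 2 * eps) + eps
    bce_mat = -(pos_weight * targets * p_hat.log()
                + (1.0 - targets) * (1.0 - p_hat).log())
    bce = bce_mat.mean()

    loss = mse + cfg.beta * bce
    parts = {"mse": float(mse.value), "bce": float(bce.value), "kl": 0.0}
    if P is not None and cfg.gamma > 0:
        Q = model.soft_assign_t(out["Z_refined"])
        Pt = Tensor(P)
        kl = (Pt * (Tensor(np.log(np.maximum(P, 1e-300))) - Q.log())).sum() / X.shape[0]
        loss = loss + cfg.gamma * kl
        parts["kl"] = float(kl.value)
    parts["loss"] = float(loss.value)
    return loss, parts


def fit(graph: PopulationGraph, config: TrainConfig) -> ClusterState:
    """Train the full pipeline on one population graph.

    Phases: (1) reconstruction-only pretraining of both autoencoders;
    (2) k-means++ centroid initialization on the refined embedding;
    (3) joint self-supervised refinement, refreshing the target distribution
    every ``target_update_interval`` epochs and stopping early once the
    fraction of changed hard labels drops below ``stop_tol``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if not (2 <= cfg.k <= graph.n_subjects - 1):
        raise ValueError("need 2 <= k <= S-1")
    model = PGDASModel(graph.features.shape[1], cfg, rng)
    X = Tensor(graph.features)
    A_hat = Tensor(graph.A_hat)
    targets_np = (graph.W > 0).astype(float)
    n_ones = targets_np.sum()
    pos_weight = float((targets_np.size - n_ones) / n_ones) if n_ones else 1.0
    targets = Tensor(targets_np)
    history: list[dict] = []

    params, decay = model.parameters()
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay,
                decay_mask=decay)
    for epoch in range(cfg.pretrain_epochs):
        opt.zero_grad()
        loss, parts = _loss_terms(model, X, A_hat, targets, pos_weight,
                                  training=True, P=None)
        loss.backward()
        opt.step()
        history.append({"phase": "pretrain", "epoch": epoch, **parts})

    out = model.embed(X, A_hat, training=False)
    z_ref = out["Z_refined"].value
    mu, labels = init_centroids(z_ref, cfg.k, cfg.seed)
    model.centroids = Tensor(mu, requires_grad=True)
    prev_labels = labels.copy()

    params, decay = model.parameters(include_centroids=True)
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay,
                decay_mask=decay)
    P = None
    for epoch in range(cfg.max_epochs):
        if epoch % cfg.target_update_interval == 0:
            out = model.embed(X, A_hat, training=False)
            Q_np = soft_assign(out["Z_refined"].value, model.centroids.value,
                               cfg.alpha)
            hard = Q_np.argmax(axis=1)
            # revive empty clusters at the least-confident point
            for j in np.setdiff1d(np.arange(cfg.k), np.unique(hard)):
                i = int(np.argmin(Q_np.max(axis=1)))
                model.centroids.value[j] = out["Z_refined"].value[i]
                logger.warning("cluster %d empty at epoch %d; centroid re-seeded", j, epoch)
                Q_np = soft_assign(out["Z_refined"].value, model.centroids.value,
                                   cfg.alpha)
                hard = Q_np.argmax(axis=1)
            P = target_distribution(Q_np)
            changed = float(np.mean(hard != prev_labels))
            if epoch > 0 and changed < cfg.stop_tol:
                prev_labels = hard
                history.append({"phase": "train", "epoch": epoch,
                                "label_change": changed, "stopped": True})
                break
            prev_labels = hard
        opt.zero_grad()
        loss, parts = _loss_terms(model, X, A_hat, targets, pos_weight,
                                  training=True, P=P)
        loss.backward()
        opt.step()
        history.append({"phase": "train", "epoch": epoch, **parts})

    out = model.embed(X, A_hat, training=False)
    if cfg.max_epochs == 0:
        # pure pretrain + k-means++: labels come straight from the Lloyd pass
        Q_np = soft_assign(out["Z_refined"].value, model.centroids.value, cfg.alpha)
        final_labels = prev_labels
    else:
        Q_np = soft_assign(out["Z_refined"].value, model.centroids.value, cfg.alpha)
        final_labels = Q_np.argmax(axis=1)
    return ClusterState(
        Z_AE=out["Z_AE"].value, Z_GAE=out["Z_GAE"].value,
        Z_fused=out["Z_fused"].value, Z_refined=out["Z_refined"].value,
        centroids=model.centroids.value.copy(), Q=Q_np,
        P=target_distribution(Q_np), labels=final_labels.astype(int),
        history=history, config=cfg,
    )


def select_k(graph: PopulationGraph, config: TrainConfig,
             k_range=range(2, 7)) -> tuple[int, dict[int, float], dict[int, ClusterState]]:
    """Fit every K in the range and pick the silhouette-maximizing one.

    The silhouette coefficient is computed on the refined embedding with
    Euclidean distance and the hard labels. A degenerate fit — one that ends
    with fewer than K non-empty clusters — cannot witness its requested K
    and is recorded as -1 (a collapsed solution would otherwise be scored as
    a sharper low-K partition). Ties break toward smaller K.
    """
    sils: dict[int, float] = {}
    states: dict[int, ClusterState] = {}
    for k in k_range:
        if not (2 <= k <= graph.n_subjects - 1):
            raise ValueError(f"k={k} outside [2, S-1]")
        state = fit(graph, replace(config, k=k))
        states[k] = state
        labs = state.labels
        if np.unique(labs).size < k:
            sils[k] = -1.0
            logger.warning("K=%d collapsed to %d non-empty clusters; "
                           "recorded as degenerate", k, np.unique(labs).size)
        else:
            sils[k] = float(silhouette_score(state.Z_refined, labs, metric="euclidean"))
    best_k = min(sils, key=lambda k: (-sils[k], k))
    return best_k, sils, states


# -------------------------------------------------------------- persistence

def save_checkpoint(state: ClusterState, path: str | Path) -> None:
    """Bundle embeddings, centroids, assignments and config into one .npz."""
    path = Path(path)
    cfg = json.dumps(asdict(state.config)) if state.config else "{}"
    np.savez(path, Z_AE=state.Z_AE, Z_GAE=state.Z_GAE, Z_fused=state.Z_fused,
             Z_refined=state.Z_refined, centroids=state.centroids, Q=state.Q,
             P=state.P, labels=state.labels, config_json=np.array(cfg),
             history_json=np.array(json.dumps(state.history)))


def load_checkpoint(path: str | Path) -> ClusterState:
    with np.load(Path(path), allow_pickle=False) as z:
        cfg_dict = json.loads(str(z["config_json"]))
        if "ae_hidden" in cfg_dict:
            cfg_dict["ae_hidden"] = tuple(cfg_dict["ae_hidden"])
        return ClusterState(
            Z_AE=z["Z_AE"], Z_GAE=z["Z_GAE"], Z_fused=z["Z_fused"],
            Z_refined=z["Z_refined"], centroids=z["centroids"], Q=z["Q"],
            P=z["P"], labels=z["labels"],
            history=json.loads(str(z["history_json"])),
            config=TrainConfig(**cfg_dict) if cfg_dict else None,
        )
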