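"""Full model: shared layer + denoising AE + graph AE + two fusion blocks.

Architecture (full-batch; n cells, g selected genes, hidden dims 256/64/16):

    S  = relu(W_shared x_zscore)          shared dimension-reduction layer
    E1 = relu(W_enc1 S)                   denoising branch, depth 1 (64)
    H1 = tanh(A_norm S W_g1)              graph branch, depth 1 (64)
    R1 = fuse_1(H1, E1)                   attention fusion, depth 1
    E2 = W_enc2 R1 (+ Gaussian noise)     bottleneck (16); noise only in training
    H2 = tanh(A_norm H1 W_g2)             graph branch, depth 2 (16)
    Z  = R2 = fuse_2(H2, E2)              cell representation for clustering
    D  = relu(W_dec2 relu(W_dec1 Z))      decoder back to 256
    pi, mu, theta = ZINB heads(D)         mu scaled by per-cell size factors
    A_recon = sigmoid(H2 H2^T)            graph decoder

Pretraining minimises  L = L_zinb + r1 * L_graph ; fine-tuning adds the
clustering loss,  L = L_kl + r2 * (L_zinb + r1 * L_graph),  and stops early
once fewer than 1/1000 of the cells change hard label between target-
distribution refreshes.

Ablation switches: ``wo_attn`` replaces the fusion blocks with a two-layer
perceptron on the concatenated embeddings; ``wo_zinb`` swaps the likelihood
for an L2 reconstruction of the z-scored input; ``wo_res`` removes the
residual connection inside the fusion blocks; ``wo_gnn`` feeds the attention
queries/keys/values all from the denoising branch and drops the graph loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, concat
from ._optim import Adam, clip_grad_norm
from .dec import (ClusterState, kl_loss_tensor, soft_assign,
                  soft_assign_tensor, target_distribution)
from .fusion import FusionBlock
from .gae import GCNLayer, graph_loss, reconstruct_adjacency
from .nn import Linear, Module
from .preprocess import CellGraph, ProcessedDataset
from .zinb import (MU_MAX, MU_MIN, PI_MAX, PI_MIN, THETA_MAX, THETA_MIN,
                   zinb_nll_tensor)

__all__ = ["TrainConfig", "ModelOutput", "FusionAutoencoder",
           "pretrain", "finetune", "FinetuneResult", "should_stop",
           "ABLATIONS", "LABEL_CHANGE_TOL"]

ABLATIONS = ("full", "wo_attn", "wo_zinb", "wo_res", "wo_gnn")
LABEL_CHANGE_TOL = 1.0 / 1000.0


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    grad_clip_l2: float = 3.0
    r1: float = 0.1
    r2: float = 0.1
    pretrain_epochs: int = 200
    max_finetune_epochs: int = 300
    update_interval: int = 1
    seed: int = 0
    ablation: str = "full"

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}")
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("r1 and r2 must be non-negative")
        if self.pretrain_epochs < 1 or self.max_finetune_epochs < 1:
            raise ValueError("epoch counts must be >= 1")


@dataclass
class ModelOutput:
    z: Tensor
    pi: Tensor | None = None
    mu: Tensor | None = None
    theta: Tensor | None = None
    recon: Tensor | None = None      # wo_zinb reconstruction of x_zscore
    a_recon: Tensor | None = None
    e1: Tensor | None = None
    e2: Tensor | None = None
    h1: Tensor | None = None
    h2: Tensor | None = None
    attention: tuple | None = None   # per-block (M, n, n) score arrays


class _ConcatMLP(Module):
    """wo_attn substitute: R = W2 relu(W1 [H; E])."""

    def __init__(self, d: int, rng: np.random.Generator):
        self.lin1 = Linear(2 * d, d, rng)
        self.lin2 = Linear(d, d, rng)

    def __call__(self, h: Tensor, e: Tensor) -> Tensor:
        return self.lin2(self.lin1(concat([h, e], axis=1)).relu())


class FusionAutoencoder(Module):
    def __init__(self, n_genes: int, hidden_dims=(256, 64, 16), n_heads: int = 8,
                 noise_var: float = 0.01, ablation: str = "full",
                 scale_attention: bool = True, input_noise: bool = False,
                 seed: int = 0):
        if ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {ablation!r}")
        h0, h1, h2 = hidden_dims
        rng = np.random.default_rng(seed)
        self.n_genes = n_genes
        self.hidden_dims = tuple(hidden_dims)
        self.noise_var = noise_var
        self.ablation = ablation
        self.input_noise = input_noise
        self._noise_rng = np.random.default_rng(rng.integers(2**31))

        self.shared = Linear(n_genes, h0, rng)
        self.enc1 = Linear(h0, h1, rng)
        self.enc2 = Linear(h1, h2, rng)
        self.gcn1 = GCNLayer(h0, h1, rng)
        self.gcn2 = GCNLayer(h1, h2, rng)
        residual = ablation != "wo_res"
        if ablation == "wo_attn":
            self.fuse1 = _ConcatMLP(h1, rng)
            self.fuse2 = _ConcatMLP(h2, rng)
        else:
            self.fuse1 = FusionBlock(h1, n_heads, rng, residual=residual,
                                     scale_scores=scale_attention)
            self.fuse2 = FusionBlock(h2, n_heads, rng, residual=residual,
                                     scale_scores=scale_attention)
        self.dec1 = Linear(h2, h1, rng)
        self.dec2 = Linear(h1, h0, rng)
        self.head_pi = Linear(h0, n_genes, rng)
        self.head_mu = Linear(h0, n_genes, rng)
        self.head_theta = Linear(h0, n_genes, rng)
        self.head_recon = Linear(h0, n_genes, rng)

    # -- pieces ---------------------------------------------------------------
    def _noise_like(self, shape) -> np.ndarray:
        return self._noise_rng.normal(0.0, np.sqrt(self.noise_var), size=shape)

    def zinb_heads(self, d: Tensor, size_factors: np.ndarray):
        """pi = sigmoid(D W), theta = exp(D W), mu = Diag(sf) exp(D W).

        The exponentials are computed on log-clamped activations so the
        clamp bounds hold without overflow.
        """
        pi = self.head_pi(d).sigmoid().clip(PI_MIN, PI_MAX)
        theta = self.head_theta(d).clip(np.log(THETA_MIN), np.log(THETA_MAX)).exp()
        mu_gene = self.head_mu(d).clip(np.log(MU_MIN), np.log(MU_MAX)).exp()
        sf = np.asarray(size_factors, float).reshape(-1, 1)
        mu = mu_gene * sf
        return pi, mu, theta

    def dae_encode(self, x_zscore: np.ndarray, training: bool = False) -> Tensor:
        """Denoising-branch encoder alone (no graph, no fusion)."""
        x = Tensor(np.asarray(x_zscore, float))
        if training and self.input_noise:
            x = x + Tensor(self._noise_like(x.shape))
        s = self.shared(x).relu()
        e1 = self.enc1(s).relu()
        e2 = self.enc2(e1)
        if training and self.noise_var > 0:
            e2 = e2 + Tensor(self._noise_like(e2.shape))
        return e2

    # -- full forward ---------------------------------------------------------
    def forward(self, data: ProcessedDataset, graph: CellGraph,
                training: bool = False) -> ModelOutput:
        x = Tensor(data.x_zscore)
        if training and self.input_noise:
            x = x + Tensor(self._noise_like(x.shape))
        a_norm = Tensor(graph.adjacency_norm)
        wo_gnn = self.ablation == "wo_gnn"

        s = self.shared(x).relu()
        e1 = self.enc1(s).relu()
        h1 = e1 if wo_gnn else self.gcn1(s, a_norm)
        r1 = self.fuse1(h1, e1)
        e2 = self.enc2(r1)
        if training and self.noise_var > 0:
            e2 = e2 + Tensor(self._noise_like(e2.shape))
        h2 = e2 if wo_gnn else self.gcn2(h1, a_norm)
        z = self.fuse2(h2, e2)

        d = self.dec2(self.dec1(z).relu()).relu()
        out = ModelOutput(z=z, e1=e1, e2=e2, h1=h1, h2=h2)
        if self.ablation == "wo_zinb":
            out.recon = self.head_recon(d)
        else:
            out.pi, out.mu, out.theta = self.zinb_heads(d, data.size_factors)
        if not wo_gnn:
            out.a_recon = reconstruct_adjacency(h2)
        if isinstance(self.fuse1, FusionBlock):
            out.attention = (self.fuse1.last_scores, self.fuse2.last_scores)
        if not np.all(np.isfinite(out.z.data)):
            raise FloatingPointError("non-finite embedding in forward pass")
        return out

    def reconstruction_loss(self, out: ModelOutput, data: ProcessedDataset) -> Tensor:
        if self.ablation == "wo_zinb":
            diff = out.recon - Tensor(data.x_zscore)
            return (diff * diff).mean()
        return zinb_nll_tensor(data.r_prime, out.pi, out.mu, out.theta)


def _train_loss(model: FusionAutoencoder, out: ModelOutput,
                data: ProcessedDataset, graph: CellGraph, r1: float):
    """L_train = L_recon + r1 * L_graph, with components for the trace."""
    recon = model.reconstruction_loss(out, data)
    if model.ablation == "wo_gnn" or r1 == 0.0:
        return recon, float(recon.data), 0.0
    g = graph_loss(out.a_recon, Tensor(graph.adjacency))
    return recon + r1 * g, float(recon.data), float(g.data)


def pretrain(model: FusionAutoencoder, data: ProcessedDataset, graph: CellGraph,
             cfg: TrainConfig) -> dict:
    """Adam minimisation of L_zinb + r1 * L_graph; returns the loss trace."""
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = {"loss": [], "recon": [], "graph": [], "grad_norm": []}
    for _ in range(cfg.pretrain_epochs):
        out = model.forward(data, graph, training=True)
        loss, recon_val, graph_val = _train_loss(model, out, data, graph, cfg.r1)
        if not np.isfinite(loss.data):
            raise FloatingPointError("pretraining loss diverged (NaN/Inf)")
        opt.zero_grad()
        loss.backward()
        pre_norm = clip_grad_norm(opt.params, cfg.grad_clip_l2)
        opt.step()
        history["loss"].append(float(loss.data))
        history["recon"].append(recon_val)
        history["graph"].append(graph_val)
        history["grad_norm"].append(min(pre_norm, cfg.grad_clip_l2))
    return history


def should_stop(changed_fraction: float) -> bool:
    """Early-stop rule: strictly fewer than 1/1000 of labels changed."""
    return changed_fraction < LABEL_CHANGE_TOL


@dataclass
class FinetuneResult:
    labels: np.ndarray
    embedding: np.ndarray
    centers: np.ndarray
    q: np.ndarray
    cluster_count_trajectory: list[int] = field(default_factory=list)
    changed_fraction_trace: list[float] = field(default_factory=list)
    loss_trace: list[float] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)
    n_epochs: int = 0
    converged: bool = False


def finetune(model: FusionAutoencoder, data: ProcessedDataset, graph: CellGraph,
             cfg: TrainConfig, state: ClusterState) -> FinetuneResult:
    """DEC fine-tuning: L = L_kl + r2 * (L_recon + r1 * L_graph).

    The target distribution P is refreshed every ``update_interval`` epochs;
    at each refresh empty clusters are dropped permanently and the stop rule
    is evaluated on the fraction of cells whose hard label changed since the
    previous refresh.
    """
    if state.n_clusters < 1:
        raise ValueError("empty initial clustering")
    centers = Tensor(np.asarray(state.centers, float).copy(), requires_grad=True)
    center_ids = state.center_ids.copy()
    opt = Adam(model.parameters() + [centers], lr=cfg.learning_rate)

    z_eval = model.forward(data, graph, training=False).z.data
    q = soft_assign(z_eval, centers.data)
    prev_ids = center_ids[np.argmax(q, axis=1)]
    p = target_distribution(q)

    res = FinetuneResult(labels=prev_ids, embedding=z_eval, centers=centers.data,
                         q=q, cluster_count_trajectory=[len(center_ids)])
    for epoch in range(cfg.max_finetune_epochs):
        out = model.forward(data, graph, training=True)
        q_t = soft_assign_tensor(out.z, centers)
        train_part, _, _ = _train_loss(model, out, data, graph, cfg.r1)
        loss = kl_loss_tensor(p, q_t) + cfg.r2 * train_part
        if not np.isfinite(loss.data):
            raise FloatingPointError("fine-tuning loss diverged (NaN/Inf)")
        opt.zero_grad()
        loss.backward()
        pre_norm = clip_grad_norm(opt.params, cfg.grad_clip_l2)
        opt.step()
        res.loss_trace.append(float(loss.data))
        res.grad_norms.append(min(pre_norm, cfg.grad_clip_l2))
        res.n_epochs = epoch + 1

        if (epoch + 1) % cfg.update_interval != 0:
            continue
        z_eval = model.forward(data, graph, training=False).z.data
        q = soft_assign(z_eval, centers.data)
        hard = np.argmax(q, axis=1)
        counts = np.bincount(hard, minlength=centers.data.shape[0])
        if np.any(counts == 0):  # empty clusters are discarded for good
            keep = counts > 0
            new_centers = Tensor(centers.data[keep].copy(), requires_grad=True)
            opt.replace_param(centers, new_centers)
            centers = new_centers
            center_ids = center_ids[keep]
            q = soft_assign(z_eval, centers.data)
            hard = np.argmax(q, axis=1)
        stable = center_ids[hard]
        changed = float(np.mean(stable != prev_ids))
        res.changed_fraction_trace.append(changed)
        res.cluster_count_trajectory.append(len(center_ids))
        p = target_distribution(q)
        prev_ids = stable
        if should_stop(changed):
            res.converged = True
            break

    # final state, with labels relabelled to consecutive integers
    z_eval = model.forward(data, graph, training=False).z.data
    q = soft_assign(z_eval, centers.data)
    hard = np.argmax(q, axis=1)
    used = np.unique(hard)
    remap = {old: new for new, old in enumerate(used)}
    res.labels = np.array([remap[h] for h in hard])
    res.embedding = z_eval
    res.centers = centers.data[used]
    res.q = q[:, used] / q[:, used].sum(axis=1, keepdims=True)
    return res
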