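"""Leiden-initialised deep embedded clustering (DEC).

Cluster centers are initialised by Leiden community detection on a Gaussian-
kernel KNN graph built over the pretrained embedding, so no cluster count is
specified.  Soft assignments use a Student-t kernel with one degree of
freedom,

    q_ij = (1 + ||z_i - kappa_j||^2)^-1 / sum_c (1 + ||z_i - kappa_c||^2)^-1,

the target distribution sharpens Q by squaring and renormalising per cluster
frequency, and fine-tuning minimises KL(P || Q).  Centers whose hard-
assignment count drops to zero are discarded and never resurrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np

from ._autograd import Tensor
from .preprocess import build_cell_graph

__all__ = [
    "ClusterState", "init_centers", "leiden_partition", "soft_assign",
    "soft_assign_tensor", "target_distribution", "kl_loss", "kl_loss_tensor",
    "hard_labels_and_change",
]

Q_FLOOR = 1e-12


@dataclass
class ClusterState:
    centers: np.ndarray                 # (k, d)
    labels: np.ndarray                  # (n,) hard labels
    resolution: float = 1.0
    q: np.ndarray | None = None
    p: np.ndarray | None = None
    changed_fraction: float = float("nan")
    center_ids: np.ndarray = field(default=None)  # stable ids across drops

    def __post_init__(self):
        if self.center_ids is None:
            self.center_ids = np.arange(self.centers.shape[0])

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def leiden_partition(z: np.ndarray, resolution: float = 1.0, seed: int = 0,
                     k: int = 15) -> np.ndarray:
    """Leiden communities on the adaptive Gaussian KNN graph over ``z``."""
    n = z.shape[0]
    k_eff = min(k, n - 1)
    graph = build_cell_graph(np.asarray(z, float), k=k_eff, random_state=seed)
    a = graph.adjacency.copy()
    np.fill_diagonal(a, 0.0)  # self-loops carry no community information
    src, dst = np.nonzero(np.triu(a))
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=a[src, dst].tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def init_centers(z: np.ndarray, resolution: float = 1.0, seed: int = 0,
                 k: int = 15) -> ClusterState:
    """Cluster centers = community means of the pretrained embedding."""
    labels = leiden_partition(z, resolution=resolution, seed=seed, k=k)
    n_comm = labels.max() + 1
    if n_comm == 1:
        warnings.warn("Leiden found a single community; proceeding with k=1")
    centers = np.stack([z[labels == j].mean(axis=0) for j in range(n_comm)])
    return ClusterState(centers=centers, labels=labels, resolution=resolution)


def _sq_dists(z: np.ndarray, centers: np.ndarray) -> np.ndarray:
    diff = z[:, None, :] - centers[None, :, :]
    return (diff**2).sum(axis=2)


def soft_assign(z: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Student-t (df=1) soft assignment; rows sum to one."""
    num = 1.0 / (1.0 + _sq_dists(np.asarray(z, float), np.asarray(centers, float)))
    return num / num.sum(axis=1, keepdims=True)


def soft_assign_tensor(z: Tensor, centers: Tensor) -> Tensor:
    """Autograd soft assignment (gradients flow to both z and centers)."""
    z_sq = (z * z).sum(axis=1, keepdims=True)          # (n, 1)
    c_sq = (centers * centers).sum(axis=1, keepdims=True).T  # (1, k)
    d2 = z_sq + c_sq - 2.0 * (z @ centers.T)
    num = (1.0 + d2) ** -1.0
    return num / num.sum(axis=1, keepdims=True)


def target_distribution(q: np.ndarray) -> np.ndarray:
    """Sharpened target P: square Q, normalise by cluster frequency."""
    q = np.asarray(q, float)
    f = q.sum(axis=0)
    keep = f > 0
    w = np.zeros_like(q)
    w[:, keep] = q[:, keep] ** 2 / f[keep]
    return w / w.sum(axis=1, keepdims=True)


def kl_loss(p: np.ndarray, q: np.ndarray) -> float:
    p = np.asarray(p, float)
    q = np.clip(np.asarray(q, float), Q_FLOOR, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
    return float(terms.sum())


def kl_loss_tensor(p: np.ndarray, q: Tensor) -> Tensor:
    """KL(P || Q) with P a constant; differentiates through Q."""
    p = np.asarray(p, float)
    logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    return (p * (logp - q.clip(Q_FLOOR, np.inf).log())).sum()


def hard_labels_and_change(q: np.ndarray, previous_labels: np.ndarray | None
                           ) -> tuple[np.ndarray, float]:
    """Argmax labels (ties -> lowest index) and fraction changed."""
    labels = np.argmax(q, axis=1)
    if previous_labels is None:
        return labels, float("nan")
    changed = float(np.mean(labels != np.asarray(previous_labels)))
    return labels, changed
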