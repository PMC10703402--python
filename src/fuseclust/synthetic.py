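"""Clustered zero-inflated negative binomial count simulator and perturbations.

The generator emulates droplet/plate scRNA-seq count matrices at the scale of
typical benchmark datasets (hundreds to thousands of cells, a handful of cell
groups).  Per cluster, each gene receives a log-mean offset drawn from
N(0, logfc_scale^2) around a shared baseline; per cell, a lognormal library
factor scales all means; counts are negative binomial (gamma–Poisson) with
dispersion ``theta_sim`` and are then zeroed independently with probability
``dropout_pi_sim`` (technical dropout).  Ground-truth cluster labels are
returned for external evaluation.

Two perturbation protocols used in robustness experiments are included:
random manual dropout of a fixed fraction of the non-zero entries, and
stratified down-sampling of cells that preserves class proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import RawCountMatrix

__all__ = ["SimSpec", "simulate_counts", "manual_dropout", "stratified_downsample"]


@dataclass
class SimSpec:
    n_cells: int = 600
    n_genes: int = 300
    n_clusters: int = 5
    cluster_proportions: tuple | None = None  # None -> uniform
    logmean_base: float = 0.0
    logfc_scale: float = 1.0       # cluster separation (sd of log-fold offsets)
    theta_sim: float = 2.0         # NB dispersion
    dropout_pi_sim: float = 0.3    # technical zero probability
    libsize_lognormal_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters > self.n_cells:
            raise ValueError("more clusters than cells")
        if not (0 <= self.dropout_pi_sim < 1):
            raise ValueError("dropout_pi_sim must be in [0, 1)")
        if self.cluster_proportions is not None:
            props = np.asarray(self.cluster_proportions, float)
            if len(props) != self.n_clusters or not np.isclose(props.sum(), 1.0):
                raise ValueError("cluster_proportions must be a simplex vector "
                                 "of length n_clusters")


def simulate_counts(spec: SimSpec) -> tuple[RawCountMatrix, np.ndarray]:
    """Draw a clustered ZINB count matrix; returns (counts, true labels)."""
    rng = np.random.default_rng(spec.seed)
    k, n, g = spec.n_clusters, spec.n_cells, spec.n_genes
    props = (np.full(k, 1.0 / k) if spec.cluster_proportions is None
             else np.asarray(spec.cluster_proportions, float))
    labels = rng.choice(k, size=n, p=props)

    log_means = spec.logmean_base + rng.normal(0.0, spec.logfc_scale, size=(k, g))
    lib = rng.lognormal(mean=0.0, sigma=spec.libsize_lognormal_sigma, size=n)
    mean = lib[:, None] * np.exp(log_means)[labels]

    # NB as gamma-Poisson mixture
    lam = rng.gamma(shape=spec.theta_sim, scale=mean / spec.theta_sim)
    counts = rng.poisson(lam).astype(np.int64)
    if spec.dropout_pi_sim > 0:
        counts[rng.random(size=counts.shape) < spec.dropout_pi_sim] = 0

    raw = RawCountMatrix(
        counts=counts,
        cell_ids=[f"cell_{i}" for i in range(n)],
        gene_ids=[f"gene_{j}" for j in range(g)],
        labels=labels,
    )
    return raw, labels


def manual_dropout(counts: np.ndarray, rate: float, seed: int = 0) -> np.ndarray:
    """Zero out exactly floor(rate * nnz) uniformly chosen non-zero entries."""
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    counts = np.array(counts, copy=True)
    if rate == 0:
        return counts
    nz = np.flatnonzero(counts)
    n_zero = int(np.floor(rate * nz.size))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(nz, size=n_zero, replace=False)
    counts.flat[chosen] = 0
    return counts


def stratified_downsample(counts: np.ndarray, labels: np.ndarray, fraction: float,
                          seed: int = 0) -> np.ndarray:
    """Per-class sampling without replacement; returns sorted cell indices.

    Each class contributes round(fraction * class size) cells, but at least
    one, so class proportions are preserved up to rounding.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_take = max(1, int(round(fraction * idx.size)))
        chosen.append(rng.choice(idx, size=n_take, replace=False))
    return np.sort(np.concatenate(chosen))
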