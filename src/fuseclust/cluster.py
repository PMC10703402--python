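"""scikit-learn style estimator wrapping the whole clustering pipeline.

``FusionAttentionClustering`` takes a raw cells x genes count matrix and
produces cluster labels without a pre-specified cluster count: preprocessing
(filtering, normalisation, variable-gene selection, z-scoring, Gaussian-
kernel cell graph), pretraining of the attention-fused denoising/graph
autoencoder, Leiden initialisation of cluster centers on the pretrained
embedding, and deep embedded clustering fine-tuning with early stopping.

The estimator follows sklearn conventions (``fit`` / ``fit_predict`` /
``predict``, ``get_params``/``set_params`` via ``BaseEstimator``, fitted
attributes with trailing underscores) and composes with sklearn model
selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from . import dec, network
from .preprocess import (RawCountMatrix, build_cell_graph, filter_empty,
                         normalize_and_select, zscore)

__all__ = ["FusionAttentionClustering"]


def _as_raw(X) -> RawCountMatrix:
    if isinstance(X, RawCountMatrix):
        return X
    try:  # AnnData-like
        import anndata

        if isinstance(X, anndata.AnnData):
            counts = X.X
            if hasattr(counts, "toarray"):
                counts = counts.toarray()
            return RawCountMatrix(
                counts=np.asarray(counts),
                cell_ids=[str(c) for c in X.obs_names],
                gene_ids=[str(g) for g in X.var_names],
            )
    except ImportError:  # pragma: no cover
        pass
    return RawCountMatrix(counts=np.asarray(X))


class FusionAttentionClustering(ClusterMixin, BaseEstimator):
    """Attention-fused ZINB/graph autoencoder clustering of scRNA-seq counts.

    Parameters
    ----------
    n_hvg : number of most-variable genes kept (all genes if fewer exist).
    k_neighbors : KNN size for the Gaussian-kernel cell graph; the adaptive
        kernel width per cell is its distance to the k-th neighbour.
    n_heads : attention heads per information-fusion block.
    hidden_dims : encoder widths (shared, depth-1, bottleneck); the decoder
        mirrors them.
    resolution : Leiden resolution for center initialisation.
    r1, r2 : loss-balance factors (graph loss in pretraining; pretraining
        loss inside the clustering stage).
    learning_rate, grad_clip_l2 : Adam step size and global L2 clip norm.
    pretrain_epochs, max_finetune_epochs, update_interval : schedule; the
        clustering stage stops early once fewer than 1/1000 of the cells
        change hard label between refreshes.
    noise_var : variance of the Gaussian noise injected at the bottleneck
        during training.
    pca_components : dimensionality of the PCA space in which cell-cell
        distances are measured for graph construction.
    ablation : one of {"full", "wo_attn", "wo_zinb", "wo_res", "wo_gnn"}.
    random_state : seed for all stochastic components; identical seeds give
        identical labels and embeddings.

    Attributes
    ----------
    labels_ : final hard cluster labels (consecutive integers).
    embedding_ : (n, bottleneck) cell representation used for clustering.
    n_clusters_ : number of non-empty clusters found.
    cluster_centers_ : (n_clusters_, bottleneck) centers.
    init_labels_ : Leiden labels that initialised the clustering stage.
    cluster_count_trajectory_ : non-empty cluster count at each refresh.
    pretrain_history_, finetune_history_ : loss/gradient traces.
    attention_scores_ : per-block (heads, n, n) attention matrices from the
        final evaluation pass (None for wo_attn).
    """

    def __init__(self, n_hvg: int = 2500, k_neighbors: int = 15,
                 n_heads: int = 8, hidden_dims: tuple = (256, 64, 16),
                 resolution: float = 1.0, r1: float = 0.1, r2: float = 0.1,
                 learning_rate: float = 1e-3, grad_clip_l2: float = 3.0,
                 pretrain_epochs: int = 200, max_finetune_epochs: int = 300,
                 update_interval: int = 1, noise_var: float = 0.01,
                 pca_components: int = 50, ablation: str = "full",
                 scale_attention: bool = True, random_state: int = 0,
                 verbose: bool = False):
        self.n_hvg = n_hvg
        self.k_neighbors = k_neighbors
        self.n_heads = n_heads
        self.hidden_dims = hidden_dims
        self.resolution = resolution
        self.r1 = r1
        self.r2 = r2
        self.learning_rate = learning_rate
        self.grad_clip_l2 = grad_clip_l2
        self.pretrain_epochs = pretrain_epochs
        self.max_finetune_epochs = max_finetune_epochs
        self.update_interval = update_interval
        self.noise_var = noise_var
        self.pca_components = pca_components
        self.ablation = ablation
        self.scale_attention = scale_attention
        self.random_state = random_state
        self.verbose = verbose

    # -- pipeline -------------------------------------------------------------
    def _train_config(self) -> network.TrainConfig:
        return network.TrainConfig(
            learning_rate=self.learning_rate, grad_clip_l2=self.grad_clip_l2,
            r1=self.r1, r2=self.r2, pretrain_epochs=self.pretrain_epochs,
            max_finetune_epochs=self.max_finetune_epochs,
            update_interval=self.update_interval, seed=self.random_state,
            ablation=self.ablation)

    def fit(self, X, y=None):
        raw = _as_raw(X)
        filtered = filter_empty(raw)
        data = normalize_and_select(filtered, n_hvg=self.n_hvg)
        graph = build_cell_graph(data, k=self.k_neighbors,
                                 n_pca=self.pca_components,
                                 random_state=self.random_state)
        cfg = self._train_config()

        model = network.FusionAutoencoder(
            n_genes=data.r_prime.shape[1], hidden_dims=self.hidden_dims,
            n_heads=self.n_heads, noise_var=self.noise_var,
            ablation=self.ablation, scale_attention=self.scale_attention,
            seed=self.random_state)
        self.pretrain_history_ = network.pretrain(model, data, graph, cfg)

        z0 = model.forward(data, graph, training=False).z.data
        state = dec.init_centers(z0, resolution=self.resolution,
                                 seed=self.random_state, k=self.k_neighbors)
        self.init_labels_ = state.labels
        if self.verbose:
            print(f"pretrain done; Leiden initialised {state.n_clusters} centers")

        result = network.finetune(model, data, graph, cfg, state)

        # book-keeping needed to embed unseen cells (label transfer)
        orig_pos = {g: j for j, g in enumerate(raw.gene_ids)}
        self.selected_genes_ = list(data.selected_genes)
        self.gene_index_ = np.array([orig_pos[g] for g in data.selected_genes])
        self.gene_means_ = data.gene_means
        self.gene_stds_ = data.gene_stds
        self.median_library_ = data.median_library

        self.model_ = model
        self.data_ = data
        self.graph_ = graph
        self.cell_ids_ = list(data.cell_ids)
        self.labels_ = result.labels
        self.embedding_ = result.embedding
        self.cluster_centers_ = result.centers
        self.n_clusters_ = result.centers.shape[0]
        self.soft_assignments_ = result.q
        self.cluster_count_trajectory_ = result.cluster_count_trajectory
        self.finetune_history_ = {
            "loss": result.loss_trace,
            "grad_norm": result.grad_norms,
            "changed_fraction": result.changed_fraction_trace,
            "n_epochs": result.n_epochs,
            "converged": result.converged,
        }
        out = model.forward(data, graph, training=False)
        self.attention_scores_ = out.attention
        self.size_factors_ = data.size_factors
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_

    # -- label transfer for unseen cells --------------------------------------
    def embed(self, X) -> np.ndarray:
        """Embed new cells with the trained network (their own cell graph)."""
        raw = _as_raw(X)
        if raw.counts.shape[1] == len(self.gene_index_):
            counts = np.asarray(raw.counts)  # already restricted to the genes
        else:
            counts = np.asarray(raw.counts)[:, self.gene_index_]
        lib = np.asarray(raw.counts).sum(axis=1).astype(float)
        sf = np.maximum(lib / self.median_library_, 1e-12)
        x_norm = np.log1p(counts / sf[:, None])
        std = np.where(self.gene_stds_ > 0, self.gene_stds_, 1.0)
        x_z = np.where(self.gene_stds_ > 0,
                       (x_norm - self.gene_means_) / std, 0.0)
        from .preprocess import ProcessedDataset

        data = ProcessedDataset(x_norm=x_norm, x_zscore=x_z, r_prime=counts,
                                size_factors=sf,
                                selected_genes=self.selected_genes_)
        k = min(self.k_neighbors, x_z.shape[0] - 1)
        graph = build_cell_graph(data, k=k, n_pca=self.pca_components,
                                 random_state=self.random_state)
        return self.model_.forward(data, graph, training=False).z.data

    def predict(self, X) -> np.ndarray:
        """Assign unseen cells to the learned centers (nearest-centroid
        transfer via the Student-t soft assignment)."""
        z = self.embed(X)
        q = dec.soft_assign(z, self.cluster_centers_)
        return np.argmax(q, axis=1)
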