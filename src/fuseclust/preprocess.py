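"""Count-matrix preprocessing and cell–cell graph construction.

The pipeline mirrors the standard scRNA-seq workflow: drop empty cells and
genes, library-size normalise each cell to the median library, log1p, keep
the most variable genes, z-score per gene, and build a weighted K-nearest
neighbour graph with an adaptive-width Gaussian kernel.  The graph and its
symmetric normalisation feed the graph-convolutional branch of the model;
the z-scored expression feeds the denoising branch; the raw counts of the
selected genes are the target of the zero-inflated negative binomial
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "RawCountMatrix",
    "ProcessedDataset",
    "CellGraph",
    "EmptyDatasetError",
    "filter_empty",
    "normalize_and_select",
    "zscore",
    "build_cell_graph",
    "preprocess",
]

SIGMA_FLOOR = 1e-12


class EmptyDatasetError(ValueError):
    """All cells or all genes were removed by filtering."""


@dataclass
class RawCountMatrix:
    """Non-negative integer counts, cells in rows, genes in columns."""

    counts: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        n, m = self.counts.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(m)]
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
        self.validate()

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integers")
        n, m = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != m:
            raise ValueError("identifier lengths must match matrix dimensions")
        if len(set(self.cell_ids)) != n or len(set(self.gene_ids)) != m:
            raise ValueError("identifiers must be unique")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length must match the number of cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class ProcessedDataset:
    x_norm: np.ndarray        # normalised, log1p, selected genes
    x_zscore: np.ndarray      # per-gene standardised x_norm
    r_prime: np.ndarray       # raw counts of the selected genes
    size_factors: np.ndarray  # library size / median library size
    selected_genes: list[str]
    cell_ids: list[str] = field(default_factory=list)
    gene_means: np.ndarray | None = None   # z-score statistics, kept so a
    gene_stds: np.ndarray | None = None    # model can embed unseen cells
    median_library: float = 0.0

    @property
    def n_cells(self) -> int:
        return self.x_zscore.shape[0]


@dataclass
class CellGraph:
    adjacency: np.ndarray       # A, symmetric, entries in [0, 1]
    adjacency_norm: np.ndarray  # D^-1/2 A D^-1/2
    k_neighbors: int
    per_cell_sigma: np.ndarray


def filter_empty(raw: RawCountMatrix) -> RawCountMatrix:
    """Drop cells and genes whose total count is zero, preserving order."""
    keep_cells = np.asarray(raw.counts).sum(axis=1) > 0
    keep_genes = np.asarray(raw.counts).sum(axis=0) > 0
    if not keep_cells.any() or not keep_genes.any():
        raise EmptyDatasetError("filtering removed every cell or every gene")
    labels = raw.labels[keep_cells] if raw.labels is not None else None
    return RawCountMatrix(
        counts=raw.counts[np.ix_(keep_cells, keep_genes)],
        cell_ids=[c for c, k in zip(raw.cell_ids, keep_cells) if k],
        gene_ids=[g for g, k in zip(raw.gene_ids, keep_genes) if k],
        labels=labels,
    )


def _dispersion(norm_counts: np.ndarray) -> np.ndarray:
    """Variance-to-mean dispersion of library-normalised counts, per gene."""
    mean = norm_counts.mean(axis=0)
    var = norm_counts.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return disp


def normalize_and_select(raw: RawCountMatrix, n_hvg: int = 2500) -> ProcessedDataset:
    """Library-normalise, log1p, and keep the ``n_hvg`` most variable genes.

    Each cell is scaled to the median library size; the per-cell size factor
    (library size / median library size) is retained because the ZINB mean is
    later rescaled by it.  Gene variability is ranked by the variance/mean
    dispersion of the normalised counts; ties break on gene order.
    """
    counts = np.asarray(raw.counts, dtype=np.float64)
    lib = counts.sum(axis=1)
    if np.any(lib <= 0):
        raise RuntimeError("zero library size after filtering")
    median_lib = float(np.median(lib))
    size_factors = lib / median_lib
    norm = counts / size_factors[:, None]

    disp = _dispersion(norm)
    n_keep = min(n_hvg, counts.shape[1])
    # stable sort on negated dispersion -> ties resolve to the earlier gene
    order = np.argsort(-disp, kind="stable")[:n_keep]
    order = np.sort(order)  # keep original gene order among the selected

    x_norm = np.log1p(norm[:, order])
    return ProcessedDataset(
        x_norm=x_norm,
        x_zscore=zscore(x_norm),
        r_prime=raw.counts[:, order],
        size_factors=size_factors,
        selected_genes=[raw.gene_ids[j] for j in order],
        cell_ids=list(raw.cell_ids),
        gene_means=x_norm.mean(axis=0),
        gene_stds=x_norm.std(axis=0),
        median_library=median_lib,
    )


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardise each column to mean 0, variance 1 (population std).

    Constant columns become all-zero.
    """
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    out = np.where(std > 0, (x - mean) / np.where(std > 0, std, 1.0), 0.0)
    return out


def _pairwise_sq_dists(y: np.ndarray) -> np.ndarray:
    sq = (y**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * y @ y.T
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def reduce_for_distances(x_zscore: np.ndarray, n_components: int = 50,
                         random_state: int = 0) -> np.ndarray:
    """Project to the top principal components before measuring distances."""
    n, m = x_zscore.shape
    k = min(n_components, n - 1 if n > 1 else 1, m)
    if k >= m:
        return np.asarray(x_zscore, dtype=np.float64)
    pca = PCA(n_components=k, svd_solver="full", random_state=random_state)
    return pca.fit_transform(x_zscore)


def build_cell_graph(x: ProcessedDataset | np.ndarray, k: int = 15,
                     n_pca: int = 50, random_state: int = 0) -> CellGraph:
    """Adaptive-width Gaussian-kernel KNN graph over cells.

    Distances are Euclidean in the top ``n_pca`` principal components.  The
    per-cell width sigma_i is the distance to the k-th nearest neighbour and
    the edge weight between cells i and j is exp(-d_ij^2 / (2 sigma_i sigma_j)),
    kept only within the union of the two cells' neighbourhoods, then
    symmetrised as (A + A^T)/2 with unit self-loops.  The normalised adjacency
    is D^-1/2 A D^-1/2.
    """
    feats = x.x_zscore if isinstance(x, ProcessedDataset) else np.asarray(x, float)
    n = feats.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells n={n}")
    y = reduce_for_distances(feats, n_components=n_pca, random_state=random_state)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(y)
    dist, idx = nn.kneighbors(y)  # column 0 is the point itself
    sigma = np.maximum(dist[:, k], SIGMA_FLOOR)

    d2 = _pairwise_sq_dists(y)
    denom = 2.0 * np.outer(sigma, sigma)
    kernel = np.exp(-d2 / denom)

    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    mask[rows, cols] = True
    mask |= mask.T  # union of neighbourhoods

    a = np.where(mask, kernel, 0.0)
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 1.0)

    deg = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    a_norm = a * np.outer(inv_sqrt, inv_sqrt)
    return CellGraph(adjacency=a, adjacency_norm=a_norm,
                     k_neighbors=k, per_cell_sigma=sigma)


def preprocess(raw: RawCountMatrix, n_hvg: int = 2500, k: int = 15,
               n_pca: int = 50, random_state: int = 0
               ) -> tuple[ProcessedDataset, CellGraph]:
    """Full preprocessing: filter, normalise/select, z-score, build graph."""
    filtered = filter_empty(raw)
    data = normalize_and_select(filtered, n_hvg=n_hvg)
    graph = build_cell_graph(data, k=k, n_pca=n_pca, random_state=random_state)
    return data, graph
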