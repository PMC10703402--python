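# Methods

## Model

`fuseclust` clusters a cells × genes raw count matrix by learning a
16-dimensional cell representation from two complementary views and
self-optimising cluster assignments on it.

**Preprocessing.** Cells and genes with zero total count are removed. Each
cell is scaled to the median library size (the per-cell size factor
`s_i = lib_i / median(lib)` is kept), expression is log1p-transformed, the
`n_hvg` most variable genes are selected, and each selected gene is z-scored
to mean 0 / variance 1 (population moments; constant genes map to 0). Gene
variability is ranked by the variance-to-mean dispersion of the normalised
counts, with ties broken by gene order — a deliberately simple, exactly
reproducible criterion (binned variants differ mainly when mean-expression
confounding is strong, which the simulated data do not exhibit).

**Cell–cell graph.** Distances are Euclidean in the top `pca_components=50`
principal components of the z-scored matrix (fewer when the data are
smaller). Each cell's kernel width σ_i is its distance to the k-th nearest
neighbour (`k_neighbors=15`); the edge weight between cells i and j is
`exp(−d_ij² / (2·σ_i·σ_j))`, retained only within the union of the two
neighbourhoods, then symmetrised as (A+Aᵀ)/2. Unit self-loops are added so
every cell passes its own message through the graph convolution; the
normalised adjacency is `Ã = D̂^{−1/2} A D̂^{−1/2}`. Duplicate cells would
give σ = 0, so σ is floored at 1e−12. The distance space (PCA vs raw genes)
is configurable; PCA is the default because the kernel is far better behaved
in a decorrelated low-dimensional space.

**Network.** A shared linear layer reduces the input to 256 dimensions and
feeds both branches. The denoising branch applies fully connected ReLU
layers 256→64 (E¹) and, after fusion, 64→16 (E²); the graph branch applies
two graph convolutions `tanh(Ã H W)` 256→64 (H¹) and 64→16 (H²). Two fusion
blocks combine the branches at matching depths: per head, queries are
projected from the topological embedding and keys/values from the denoising
embedding, scores are `softmax(QKᵀ/√d_head)` over all cells, and the block
output is the projected concatenation of the attended values plus the
denoising embedding as a residual. The second block's output Z is the cell
representation. A mirrored ReLU decoder (16→64→256) ends in three heads:
`π = sigmoid(DW_π)`, `θ = exp(DW_θ)`, `μ = Diag(s)·exp(DW_μ)` — the mean is
rescaled per cell by its size factor so the likelihood is evaluated against
raw counts. The graph decoder reconstructs `sigmoid(H² H²ᵀ)`.

Layer widths are 256/64/16 with 8 attention heads (so d_head is 8 and 2 at
the two depths; widths must divide the head count). Bottleneck and fusion
outputs are linear; ReLU is used between the wider layers. Gaussian noise
with mean 0 and variance 0.01 is added to the bottleneck embedding E²
during training only, which makes the reconstruction objective denoising;
input-level corruption is available (`input_noise`) but off by default.

**Losses.** The ZINB negative log-likelihood is averaged over all matrix
entries (a mean rather than a sum keeps the balance factors scale-free):
the x = 0 branch is computed with log-sum-exp over
{log π, log(1−π) + θ(log θ − log(θ+μ))} and the positive branch with
log-gamma terms. Parameters are clamped to π ∈ [1e−6, 1−1e−6],
θ ∈ [1e−4, 1e6], μ ∈ [1e−6, 1e6] (applied on the log scale before
exponentiation, so no overflow occurs). The graph loss is the mean squared
error between A and its reconstruction. Pretraining minimises
`L_zinb + r₁·L_graph` with Adam (lr 0.001) and global L2 gradient clipping
at 3.

**Clustering stage.** Leiden community detection (leidenalg,
RBConfiguration partition, seeded, resolution 1.0) on a Gaussian-kernel KNN
graph over the pretrained embedding initialises the centers as community
means — no cluster count is supplied. At resolution 1 the initial partition
is often finer than the true structure; this is expected, and redundant
centers are merged away during fine-tuning. Fine-tuning minimises
`KL(P‖Q) + r₂·(L_zinb + r₁·L_graph)` where Q is the Student-t (df = 1) soft
assignment to the centers and P the sharpened target, refreshed every
`update_interval=1` epochs. At each refresh, centers with zero hard
assignments are dropped permanently (the non-empty count trajectory is
recorded), and training stops once strictly fewer than 1/1000 of cells
changed hard label since the previous refresh, or at
`max_finetune_epochs=300`. Argmax ties resolve to the lowest cluster index.

**Ablations.** `wo_attn` replaces each fusion block by a two-layer
perceptron on the concatenated embeddings (no residual — the substitute is
the block as a whole); `wo_zinb` swaps the likelihood for an L2
reconstruction of the z-scored input; `wo_res` removes the residual inside
the fusion blocks; `wo_gnn` feeds queries, keys and values all from the
denoising embedding and omits the graph loss.

## Numerical engine

Training runs on a compact reverse-mode automatic-differentiation engine
over numpy float64 arrays (`fuseclust._autograd`), with Adam and global-norm
clipping in `fuseclust._optim`. All gradients are validated against central
finite differences in the test suite (relative tolerance 1e−4), including
the ZINB likelihood (log-gamma gradients via the digamma function) and the
KL/Student-t clustering loss. Training is full-batch: every epoch is one
forward/backward pass over all cells, which bounds memory at O(n²) for the
attention and adjacency matrices and keeps the method practical up to a few
thousand cells per run.

Reproducibility: a single `random_state` seeds weight initialisation, the
noise stream, PCA, and Leiden; identical seeds give bitwise-identical labels
and embeddings.

## Synthetic data

`simulate_counts` draws clustered ZINB matrices: per cluster, each gene's
log-mean is the baseline (`logmean_base=0`) plus a N(0, `logfc_scale`²)
offset; per cell, a lognormal library factor (σ = 0.3) scales all means;
counts are gamma–Poisson with dispersion `theta_sim`, then zeroed with
probability `dropout_pi_sim`. Defaults — 600 cells, 300 genes, 5 equal
clusters, θ = 2, 30% dropout, `logfc_scale=1.0` (moderate separation) —
emulate the scale and sparsity of common benchmark tissue datasets while
staying small enough to run on one CPU.

The generator matches the model's own observation assumptions (ZINB noise,
library-size variation, cluster-wise mean shifts). It does **not** emulate
batch effects, doublets, ambient RNA, mean–variance trends across genes,
gene–gene correlation within clusters, or continuous/trajectory structure —
so passing tests demonstrate correct mechanics and recoverability under the
assumed noise model, not performance on those real-data complications.

Perturbation protocols: `manual_dropout` zeroes exactly ⌊rate·nnz⌋ uniformly
chosen **non-zero** entries (zeroing arbitrary entries would make the nominal
rate meaningless on sparse data); `stratified_downsample` samples
round(fraction·class size) cells per class (at least one). After training on
a subset, labels for the full dataset are obtained by embedding all cells
with the trained network and assigning each to its nearest center via the
Student-t kernel (`predict`).

## Problem sizes and defaults used in the shipped experiments

The test suite and `scripts/acceptance.py` evaluate label recovery at the
600×300 default conditions over three seeds with full training defaults
(200 pretraining epochs), and run the multi-seed ablation/robustness
comparisons on a 400×200, 5-cluster family with 100 pretraining epochs —
sizes chosen so the whole battery runs in minutes on one CPU while leaving
the directional comparisons clearly resolved. The cluster-count trajectory
experiment uses a 200×100, 3-cluster family at separation 2.0, where
resolution-1 Leiden visibly over-partitions and fine-tuning merges the
redundant centers.

## Known limitations

- O(n²) memory/time in the cell count (dense graph + attention over all
  cells); full-batch only. Tens of thousands of cells require mini-batching
  or sparse attention, which this implementation does not provide.
- The ZINB heads assume counts; UMI-corrected or imputed input should use
  the `wo_zinb` (L2) variant.
- Leiden resolution remains the main granularity dial: very unbalanced or
  nested structure may need a value other than 1.0.
- No batch-effect correction, doublet removal or ambient-RNA handling.
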