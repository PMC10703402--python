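"""Clustering evaluation: external (ARI, NMI) and internal (silhouette, DB).

External metrics compare predicted labels against ground truth; internal
metrics score cluster geometry in the latent embedding with Euclidean
distances.  Higher ARI/NMI/silhouette and lower Davies-Bouldin indicate
better clusterings.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import (adjusted_rand_score, davies_bouldin_score,
                             normalized_mutual_info_score, silhouette_score)

__all__ = ["external_metrics", "internal_metrics"]


def external_metrics(pred_labels, true_labels, nmi_average: str = "arithmetic") -> dict:
    """Adjusted Rand index and normalised mutual information."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("label vectors must have the same length")
    return {
        "ari": float(adjusted_rand_score(true, pred)),
        "nmi": float(normalized_mutual_info_score(true, pred,
                                                  average_method=nmi_average)),
    }


def internal_metrics(embedding, pred_labels) -> dict:
    """Silhouette and Davies-Bouldin scores on the embedding."""
    z = np.asarray(embedding, float)
    labels = np.asarray(pred_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("internal metrics are undefined for a single cluster")
    return {
        "silhouette": float(silhouette_score(z, labels, metric="euclidean")),
        "davies_bouldin": float(davies_bouldin_score(z, labels)),
    }
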