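"""Latent-space visualization and clustering evaluation.

Low-dimensional views come four ways: the first k latent features verbatim,
PCA or t-SNE on the raw integrated matrix (the traditional baselines), or
t-SNE applied to the full learned LF matrix.  Cluster purity scores a seeded
k-means against known labels using the optimal one-to-one cluster-to-label
assignment, so it is invariant to cluster relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = ["Embedding2D", "select_first_lfs", "baseline_reduce",
           "tsne_on_latent", "cluster_purity", "plot_embedding"]


@dataclass
class Embedding2D:
    coordinates: np.ndarray  # samples x k (k = 2 or 3)
    method: str  # first_lfs | pca | tsne | tsne_on_lfs
    source_dimension: int


def select_first_lfs(lfs: np.ndarray, k: int = 2) -> Embedding2D:
    """Columns 1..k of the LF matrix, no re-scaling.

    Any k latent coordinates carry comparable information; the first k are a
    deterministic choice.
    """
    lfs = np.asarray(lfs)
    if k > lfs.shape[1]:
        raise ValueError(f"k={k} exceeds latent dimension {lfs.shape[1]}")
    return Embedding2D(lfs[:, :k].copy(), "first_lfs", lfs.shape[1])


def baseline_reduce(X: np.ndarray, method: str, k: int = 2, seed: int = 0) -> Embedding2D:
    """PCA (sign-fixed, deterministic) or t-SNE (deterministic under seed)."""
    X = np.asarray(X, float)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds input dimension {X.shape[1]}")
    if method == "pca":
        pca = PCA(n_components=k, svd_solver="full")
        coords = pca.fit_transform(X)
        # Sign convention: largest-magnitude loading of each component positive.
        for j in range(k):
            comp = pca.components_[j]
            if comp[np.argmax(np.abs(comp))] < 0:
                coords[:, j] *= -1
    elif method == "tsne":
        perplexity = min(30.0, max((X.shape[0] - 1) / 3.0, 2.0))
        coords = TSNE(n_components=k, random_state=seed, init="pca",
                      perplexity=perplexity).fit_transform(X)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'pca' or 'tsne'")
    return Embedding2D(np.asarray(coords, float), method, X.shape[1])


def tsne_on_latent(lfs: np.ndarray, k: int = 2, seed: int = 0) -> Embedding2D:
    """t-SNE on the full learned LF matrix (not the raw features)."""
    emb = baseline_reduce(np.asarray(lfs, float), "tsne", k=k, seed=seed)
    return Embedding2D(emb.coordinates, "tsne_on_lfs", lfs.shape[1])


def _best_assignment(contingency: np.ndarray) -> Dict[int, int]:
    """Optimal one-to-one cluster -> label map maximizing agreement."""
    rows, cols = linear_sum_assignment(-contingency)
    return dict(zip(rows.tolist(), cols.tolist()))


def cluster_purity(embedding, true_labels: np.ndarray, n_clusters: int,
                   seed: int = 0) -> Tuple[float, Dict[int, int]]:
    """K-means purity of an embedding against known labels.

    Clusters are matched to labels by the assignment maximizing agreement
    (Hungarian algorithm); accuracy is matched agreement / n.
    """
    coords = embedding.coordinates if isinstance(embedding, Embedding2D) \
        else np.asarray(embedding, float)
    true_labels = np.asarray(true_labels)
    if len(coords) < n_clusters:
        raise ValueError("fewer samples than clusters")
    uniq = np.unique(true_labels)
    if n_clusters != len(uniq):
        raise ValueError(
            f"n_clusters={n_clusters} must equal the number of distinct labels {len(uniq)}")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    assigned = km.fit_predict(coords)
    label_index = {lab: i for i, lab in enumerate(uniq)}
    cont = np.zeros((n_clusters, len(uniq)), dtype=int)
    for c, lab in zip(assigned, true_labels):
        cont[c, label_index[lab]] += 1
    mapping = _best_assignment(cont)
    correct = sum(cont[c, mapping[c]] for c in mapping)
    return correct / len(true_labels), mapping


def plot_embedding(embedding: Embedding2D, labels: np.ndarray, path,
                   label_names: Dict[int, str] = None, title: str = "") -> None:
    """Class-colored scatter plot of a 2-D embedding (vector or raster by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = embedding.coordinates
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in np.unique(labels):
        mask = labels == lab
        name = label_names.get(lab, str(lab)) if label_names else str(lab)
        ax.scatter(coords[mask, 0], coords[mask, 1], s=8, label=name, alpha=0.7)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(title or embedding.method)
    ax.legend(markerscale=2, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
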