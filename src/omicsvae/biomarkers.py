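"""Map clinically relevant latent features back to input features.

For every (CRLF, feature) pair a univariate ordinary-least-squares fit on
standardized variables is computed; the standardized slope equals the
Pearson correlation, and the slope-test p-value is recorded.  Features
significantly correlated with at least one CRLF form the biomarker map,
which is then ordered by hierarchical clustering (average linkage) for the
correlation heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = ["BiomarkerMap", "map_crlfs_to_features", "filter_biomarkers",
           "cluster_heatmap"]


@dataclass
class BiomarkerMap:
    correlations: np.ndarray  # CRLFs x retained features
    p_values: np.ndarray
    crlf_names: List[str]
    feature_provenance: List[Tuple[str, str]]  # (block/modality, feature_id)
    row_order: Optional[np.ndarray] = None  # dendrogram leaf orders
    col_order: Optional[np.ndarray] = None


def map_crlfs_to_features(crlf_matrix: np.ndarray, feature_matrix: np.ndarray
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """Pearson correlation and slope-test p for every (CRLF, feature) pair.

    Equivalent to per-pair OLS on standardized variables.  Constant features
    are recorded as r = 0, p = 1.
    """
    Z = np.asarray(crlf_matrix, float)
    X = np.asarray(feature_matrix, float)
    if Z.shape[0] != X.shape[0]:
        raise ValueError("CRLF and feature matrices have different sample counts")
    n = Z.shape[0]
    Zc = Z - Z.mean(axis=0)
    Xc = X - X.mean(axis=0)
    z_sd = Zc.std(axis=0)
    x_sd = Xc.std(axis=0)
    denom = np.outer(z_sd, x_sd) * n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Zc.T @ Xc) / denom
    r = np.nan_to_num(np.clip(r, -1.0, 1.0))
    const = (x_sd == 0)[None, :] | (z_sd == 0)[:, None]
    r[const] = 0.0
    # t statistic of the regression slope; same p as the correlation test.
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df)
    p[const] = 1.0
    return r, p


def filter_biomarkers(correlations: np.ndarray, p_values: np.ndarray,
                      provenance: Sequence[Tuple[str, str]],
                      crlf_names: Optional[Sequence[str]] = None,
                      r_threshold: float = 0.3,
                      p_threshold: float = 0.05) -> BiomarkerMap:
    """Retain features with |r| >= r_threshold and p < p_threshold for >= 1 CRLF."""
    correlations = np.asarray(correlations)
    p_values = np.asarray(p_values)
    if correlations.shape != p_values.shape:
        raise ValueError("correlation and p-value matrices are misaligned")
    keep = ((np.abs(correlations) >= r_threshold) & (p_values < p_threshold)).any(axis=0)
    if crlf_names is None:
        crlf_names = [f"LF{i}" for i in range(correlations.shape[0])]
    return BiomarkerMap(
        correlations=correlations[:, keep],
        p_values=p_values[:, keep],
        crlf_names=list(crlf_names),
        feature_provenance=[pv for pv, k in zip(provenance, keep) if k],
    )


def cluster_heatmap(bmap: BiomarkerMap, path=None) -> BiomarkerMap:
    """Average-linkage hierarchical ordering of rows and columns; optional figure.

    Returns the map with ``row_order`` / ``col_order`` filled in;
    deterministic for fixed input.
    """
    R = bmap.correlations
    if R.size == 0:
        raise ValueError("empty biomarker map")

    def leaf_order(mat):
        if mat.shape[0] < 2:
            return np.arange(mat.shape[0])
        return leaves_list(linkage(pdist(mat), method="average"))

    bmap.row_order = leaf_order(R)
    bmap.col_order = leaf_order(R.T)
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        ordered = R[np.ix_(bmap.row_order, bmap.col_order)]
        vmax = max(np.abs(R).max(), 1e-6)
        fig, ax = plt.subplots(figsize=(8, 4))
        sns.heatmap(ordered, cmap="RdBu_r", center=0, vmin=-vmax, vmax=vmax,
                    ax=ax, cbar_kws={"label": "Pearson r"})
        ax.set_xlabel("input features (clustered)")
        ax.set_ylabel("CRLFs (clustered)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return bmap
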