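"""Multilayer community detection by clustering the rows of the estimated
common subspace, and permutation-aligned misclustering evaluation.

In a multilayer SBM the common subspace basis has exactly K distinct rows,
one per community, so clustering the rows of the estimate recovers the
partition shared by all layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

__all__ = ["ClusterResult", "cluster_subspace", "misclustering_error"]


@dataclass
class ClusterResult:
    """A hard partition of the vertices with its centroids and objective."""

    Z_hat: np.ndarray
    centroids: np.ndarray
    method: str
    objective: float

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.Z_hat, axis=1)


def _one_hot(labels: np.ndarray, K: int) -> np.ndarray:
    Z = np.zeros((labels.size, K))
    Z[np.arange(labels.size), labels] = 1.0
    return Z


def cluster_subspace(
    V_hat: np.ndarray,
    K: int,
    method: str = "kmeans",
    seed: int | None = 0,
    n_restarts: int = 20,
) -> ClusterResult:
    """Cluster the rows of the subspace basis into K communities.

    K-means (default, the objective backing the misclustering guarantees)
    minimises ||Z C - V_hat||_F over one-hot Z and centroids C with
    multiple seeded restarts; "gmm" fits K full-covariance Gaussian
    components and assigns by maximum responsibility.
    """
    V_hat = np.asarray(V_hat, dtype=float)
    n = V_hat.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the number of vertices {n}")
    if method == "kmeans":
        km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(V_hat)
        centroids = km.cluster_centers_
        objective = float(np.sqrt(km.inertia_))
    elif method == "gmm":
        gm = GaussianMixture(
            n_components=K, covariance_type="full", n_init=max(1, n_restarts // 4),
            random_state=seed,
        )
        labels = gm.fit_predict(V_hat)
        centroids = gm.means_
        objective = float(
            np.linalg.norm(_one_hot(labels, K) @ centroids - V_hat, "fro")
        )
    else:
        raise ValueError("method must be 'kmeans' or 'gmm'")
    if np.unique(labels).size < K:
        warnings.warn(f"clustering produced fewer than K={K} nonempty clusters")
    return ClusterResult(
        Z_hat=_one_hot(labels, K),
        centroids=centroids,
        method=method,
        objective=objective,
    )


def misclustering_error(Z_hat, Z_true):
    """Count misclustered vertices under the best label permutation.

    Community labels are only recoverable up to permutation, so the
    estimated labels are aligned to the truth by maximising the confusion
    matrix's diagonal via optimal assignment (equivalent to minimising
    ||Z_hat - Z Q||_F over permutation matrices Q).  Differing column
    counts are handled by padding the confusion matrix with zeros.

    Returns
    -------
    (count, fraction, frobenius) — the number and fraction of misassigned
    vertices and ||Z_hat - Z Q||_F = sqrt(2 * count).
    """
    Z_hat = np.asarray(Z_hat, dtype=float)
    Z_true = np.asarray(Z_true, dtype=float)
    if Z_hat.shape[0] != Z_true.shape[0]:
        raise ValueError("partitions must cover the same vertices")
    n = Z_hat.shape[0]
    K = max(Z_hat.shape[1], Z_true.shape[1])
    confusion = Z_hat.T @ Z_true  # (K_hat, K_true) co-occurrence counts
    padded = np.zeros((K, K))
    padded[: confusion.shape[0], : confusion.shape[1]] = confusion
    rows, cols = linear_sum_assignment(-padded)
    agree = padded[rows, cols].sum()
    count = int(round(n - agree))
    return count, count / n, float(np.sqrt(2.0 * count))
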