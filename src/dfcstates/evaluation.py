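"""Clustering evaluation: Davies-Bouldin index, k-means baseline,
cross-run state matching.

The Davies-Bouldin index (DBI) scores a clustering by averaging, over
clusters, the worst ratio of within-cluster scatter to between-centroid
distance; lower is better. The default distance is correlation distance
(1 - Pearson r), consistent with the correlation similarity used by the
community clustering; Euclidean is available as an alternative. For
mean-0 / sd-1 vectors of dimension m the two are monotonically related
(1 - corr(x, y) = ||x - y||^2 / (2m)).

The k-means baseline sweeps a fixed cluster count K over a range with
multiple seeded restarts, mirroring how a fixed-K method would be
applied to the same samples; DBI per K locates the best K for
comparison with the assumption-free community clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans


@dataclass
class ClusterQualityReport:
    """DBI of both clustering steps for one method."""

    method: str
    group_dbi: list[float]
    centroid_dbi: float
    k: int | None = None
    restarts: int | None = None
    seed: int | None = None

    @property
    def mean_group_dbi(self) -> float:
        return float(np.mean(self.group_dbi))


def _pairwise_distance(X: np.ndarray, Y: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        diff = X[:, None, :] - Y[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))
    if metric == "correlation":
        Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        Yz = (Y - Y.mean(axis=1, keepdims=True)) / Y.std(axis=1, keepdims=True)
        return 1.0 - Xz @ Yz.T / X.shape[1]
    raise ValueError(f"unknown metric {metric!r}")


def davies_bouldin(
    X: np.ndarray, labels, metric: str = "correlation"
) -> float:
    """Davies-Bouldin index of a labeled sample set.

    DBI = mean_i max_{j != i} (s_i + s_j) / d_ij, with s_i the mean
    member-to-centroid distance of cluster i and d_ij the distance
    between centroids i and j. Requires >= 2 clusters; coincident
    centroids (zero between-distance) raise rather than returning inf.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("DBI undefined for a single cluster")
    centroids = np.stack([X[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array(
        [
            _pairwise_distance(
                X[labels == u], centroids[i : i + 1], metric
            ).mean()
            for i, u in enumerate(uniq)
        ]
    )
    d = _pairwise_distance(centroids, centroids, metric)
    off = ~np.eye(len(uniq), dtype=bool)
    if np.any(d[off] <= 0):
        raise ValueError("coincident cluster centroids: DBI diverges")
    ratio = (scatter[:, None] + scatter[None, :]) / np.where(off, d, np.inf)
    return float(np.max(np.where(off, ratio, -np.inf), axis=1).mean())


def kmeans_baseline(
    X: np.ndarray,
    k_range: tuple[int, int] = (1, 6),
    restarts: int = 100,
    seed: int = 0,
    dbi_metric: str = "correlation",
) -> pd.DataFrame:
    """Fixed-K k-means sweep with multi-restart, one row per K.

    Classical k-means on the (already normalized) edge vectors with
    Euclidean distance; for each K the best of ``restarts`` random
    initializations by within-cluster inertia is kept (restarts that
    hit an empty cluster are re-initialized internally by the solver).
    DBI is reported for K >= 2; K = 1 gets inertia only. Columns:
    ``k``, ``inertia``, ``dbi``, plus the label array per K in
    ``.attrs["labels"]``.
    """
    X = np.asarray(X, dtype=float)
    lo, hi = k_range
    if hi > X.shape[0]:
        raise ValueError(f"K up to {hi} requested but only {X.shape[0]} samples")
    rows = []
    all_labels = {}
    for k in range(lo, hi + 1):
        km = KMeans(
            n_clusters=k,
            n_init=restarts,
            random_state=seed,
            algorithm="lloyd",
        ).fit(X)
        dbi = (
            davies_bouldin(X, km.labels_, metric=dbi_metric)
            if k >= 2
            else np.nan
        )
        rows.append({"k": k, "inertia": float(km.inertia_), "dbi": dbi})
        all_labels[k] = km.labels_ + 1
    out = pd.DataFrame(rows)
    out.attrs["labels"] = all_labels
    return out


def cross_run_matching(
    labels_a,
    labels_b,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Best-bijection agreement between two labelings of the same items.

    The state labels of two runs are matched by maximizing the total
    confusion-matrix overlap (Hungarian assignment, rectangular if the
    state counts differ); the matching rate is the agreed fraction
    under that mapping. A permutation null (``labels_b`` shuffled)
    gives the chance level and an empirical p-value.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same item set")

    def best_overlap(x, y) -> int:
        ux, xi = np.unique(x, return_inverse=True)
        uy, yi = np.unique(y, return_inverse=True)
        conf = np.zeros((len(ux), len(uy)), dtype=int)
        np.add.at(conf, (xi, yi), 1)
        rows, cols = linear_sum_assignment(conf, maximize=True)
        return int(conf[rows, cols].sum())

    n = len(a)
    rate = best_overlap(a, b) / n
    rng = np.random.default_rng(seed)
    null = np.array(
        [best_overlap(a, rng.permutation(b)) / n for _ in range(n_permutations)]
    )
    p = (1 + np.sum(null >= rate)) / (1 + n_permutations)
    return {
        "matching_rate": float(rate),
        "null_mean": float(null.mean()),
        "p_value": float(p),
    }
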