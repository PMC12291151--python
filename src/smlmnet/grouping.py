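"""Feature normalization, K-means grouping and representative-blob retrieval.

Blobs are grouped in z-scored feature space with K-means (the user picks K,
typically from bimodal feature histograms), grouping quality is assessed by
silhouette, group mean vectors are compared by Euclidean distance, and the
blobs nearest a group's mean are retrieved as its representatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

__all__ = [
    "GroupingResult",
    "normalize_features",
    "denormalize_features",
    "kmeans_group",
    "silhouette_quality",
    "group_feature_distance",
    "retrieve_representatives",
]


@dataclass(frozen=True)
class GroupingResult:
    """K-means grouping of blobs in normalized feature space.

    labels are 1..K with group 1 the largest; group_means live in the
    normalized space; fractions sum to 1.
    """

    labels: np.ndarray
    group_means: np.ndarray
    group_fractions: np.ndarray
    silhouette_mean: float
    seed: int
    K: int


def normalize_features(matrix: np.ndarray):
    """Column z-scoring with population (n-denominator) standard deviation.

    Zero-variance columns are mapped to all-zeros and their indices
    returned so distance computations can ignore them (they carry no
    between-blob information either way).

    Returns (z, means, sds, zero_variance_columns).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("normalize_features requires at least 2 rows")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0)  # population sd
    zero_var = np.flatnonzero(sds == 0)
    safe = np.where(sds == 0, 1.0, sds)
    z = (matrix - means) / safe
    z[:, zero_var] = 0.0
    return z, means, sds, zero_var


def denormalize_features(z: np.ndarray, means: np.ndarray,
                         sds: np.ndarray) -> np.ndarray:
    """Inverse of normalize_features (zero-variance columns return the mean)."""
    return z * np.where(sds == 0, 0.0, sds) + means


def kmeans_group(z: np.ndarray, K: int, seed: int = 0,
                 n_init: int = 10) -> GroupingResult:
    """K-means (k-means++ init, n_init restarts, best inertia) on z-scores.

    Group ids are relabelled 1..K by descending group size, so "Group 1"
    is always the most populous.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of blobs ({n})")
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_init,
                random_state=seed)
    raw = km.fit_predict(z)

    sizes = np.bincount(raw, minlength=K)
    # descending size; ties broken by the raw label for determinism
    order = np.lexsort((np.arange(K), -sizes))
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(1, K + 1)
    labels = relabel[raw]

    group_means = np.vstack([z[labels == g].mean(axis=0)
                             for g in range(1, K + 1)])
    fractions = np.asarray([(labels == g).mean() for g in range(1, K + 1)])
    if K >= 2:
        sil = float(np.mean(silhouette_samples(z, labels)))
    else:
        sil = float("nan")
    return GroupingResult(
        labels=labels,
        group_means=group_means,
        group_fractions=fractions,
        silhouette_mean=sil,
        seed=seed,
        K=K,
    )


def silhouette_quality(z: np.ndarray, labels: np.ndarray):
    """Per-blob silhouette scores (Euclidean) and their mean."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 groups")
    scores = silhouette_samples(np.asarray(z, dtype=float), labels)
    return scores, float(scores.mean())


def group_feature_distance(mean_a: np.ndarray, mean_b: np.ndarray) -> float:
    """Euclidean distance between two group-mean feature vectors."""
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    if mean_a.shape != mean_b.shape:
        raise ValueError("feature-space dimension mismatch")
    return float(np.linalg.norm(mean_a - mean_b))


def retrieve_representatives(z: np.ndarray, labels: np.ndarray, group: int,
                             top_n: int,
                             blob_ids: Sequence[int] | None = None) -> List[int]:
    """The top_n blobs of a group closest to the group mean (normalized space).

    Returns blob ids sorted by ascending distance to the mean, ties broken
    by blob id; this is the "most representative blobs" retrieval.
    """
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    if blob_ids is None:
        blob_ids = np.arange(len(labels))
    blob_ids = np.asarray(blob_ids)
    members = np.flatnonzero(labels == group)
    if len(members) == 0:
        raise ValueError(f"group {group} is empty")
    if top_n > len(members):
        raise ValueError(f"top_n={top_n} exceeds group size {len(members)}")
    mean = z[members].mean(axis=0)
    dists = np.linalg.norm(z[members] - mean, axis=1)
    order = np.lexsort((blob_ids[members], dists))
    return [int(blob_ids[members[k]]) for k in order[:top_n]]
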