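"""Blob segmentation: Gaussian-kernel mean-shift and DBSCAN.

Mean-shift suits blob-like structures (nuclear pores, corners): every
localization climbs the kernel-density gradient to a mode, and points whose
modes coincide form one blob. The kernel bandwidth h is the expected
standard deviation of the structures to segment — the pore scale or the
corner scale read off Ripley's H-function. DBSCAN handles arbitrary shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .locio import LocalizationTable

__all__ = [
    "Blob",
    "mean_shift",
    "dbscan",
    "labels_to_blobs",
    "blob_labels",
    "adjacency_distances",
]

#: mean-shift iteration controls: convergence displacement (nm), iteration
#: cap, mode-fusion radius as a fraction of bandwidth, kernel support cutoff
#: in bandwidths.
MS_TOL = 0.01
MS_MAX_ITER = 300
MS_FUSE_FRACTION = 0.5
MS_SUPPORT = 3.0


@dataclass(frozen=True)
class Blob:
    """One segmented cluster: sorted member indices and their centroid."""

    id: int
    members: np.ndarray
    centroid: np.ndarray

    @property
    def n_locs(self) -> int:
        return len(self.members)


def labels_to_blobs(
    table: LocalizationTable, labels: np.ndarray, noise_label: int = -1
) -> List[Blob]:
    """Group localization indices by label into Blob objects (noise dropped).

    Blob ids are assigned 0..k-1 in order of each cluster's smallest member
    index, making the labelling invariant to the original label values.
    """
    labels = np.asarray(labels)
    blobs = []
    order = []
    for lab in np.unique(labels):
        if lab == noise_label:
            continue
        members = np.flatnonzero(labels == lab)
        order.append((members[0], members))
    order.sort(key=lambda t: t[0])
    for bid, (_, members) in enumerate(order):
        centroid = table.coords[members].mean(axis=0)
        blobs.append(Blob(id=bid, members=members, centroid=centroid))
    return blobs


def blob_labels(blobs: Sequence[Blob], n: int) -> np.ndarray:
    """Inverse of labels_to_blobs: per-localization label vector (-1 = noise)."""
    labels = np.full(n, -1, dtype=int)
    for blob in blobs:
        labels[blob.members] = blob.id
    return labels


def _gaussian_mean_shift_modes(
    coords: np.ndarray, bandwidth: float, truncate: Optional[float] = MS_SUPPORT
) -> np.ndarray:
    """Iterate every point to its Gaussian-kernel density mode.

    The update is the kernel-weighted mean of the data around the current
    position. For speed the kernel is truncated at ``truncate`` bandwidths
    (weights there are exp(-4.5) ~ 1e-2 of the peak); ``truncate=None``
    uses the full kernel, and the two must agree on test fixtures.
    """
    n, d = coords.shape
    tree = cKDTree(coords) if truncate is not None else None
    positions = coords.copy()
    active = np.ones(n, dtype=bool)
    inv2h2 = 1.0 / (2.0 * bandwidth * bandwidth)

    for _ in range(MS_MAX_ITER):
        idx_active = np.flatnonzero(active)
        if len(idx_active) == 0:
            break
        if truncate is not None:
            neighbor_lists = tree.query_ball_point(
                positions[idx_active], truncate * bandwidth
            )
        for row, i in enumerate(idx_active):
            if truncate is not None:
                nbrs = neighbor_lists[row]
                pts = coords[nbrs]
            else:
                pts = coords
            diff = pts - positions[i]
            w = np.exp(-np.einsum("ij,ij->i", diff, diff) * inv2h2)
            new = w @ pts / w.sum()
            if np.linalg.norm(new - positions[i]) < MS_TOL:
                active[i] = False
            positions[i] = new
    return positions


def _fuse_modes(modes: np.ndarray, radius: float) -> np.ndarray:
    """Greedy single-pass fusion: scan modes in index order, attach each to
    the first established mode within ``radius``, else open a new blob."""
    labels = np.full(len(modes), -1, dtype=int)
    centers: List[np.ndarray] = []
    tree = None
    rebuild_at = 0
    for i, m in enumerate(modes):
        assigned = -1
        if centers:
            if tree is None or len(centers) >= rebuild_at:
                tree = cKDTree(np.asarray(centers))
                rebuild_at = max(8, 2 * len(centers))
            cand = sorted(tree.query_ball_point(m, radius))
            # centers appended after the last tree build are checked directly
            for c in range(tree.n, len(centers)):
                if np.linalg.norm(centers[c] - m) <= radius:
                    cand.append(c)
            if cand:
                assigned = min(cand)
        if assigned < 0:
            centers.append(m)
            assigned = len(centers) - 1
        labels[i] = assigned
    return labels


def mean_shift(
    table: LocalizationTable,
    bandwidth: float,
    truncate: Optional[float] = MS_SUPPORT,
) -> List[Blob]:
    """Segment with Gaussian-kernel mean-shift; h is the kernel sd in nm.

    Every localization is iterated to its density mode; modes within h/2
    are fused into one blob, and every localization belongs to exactly one
    blob. Too large a bandwidth under-segments (fuses neighbouring
    structures); too small over-segments.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if table.n == 0:
        return []
    modes = _gaussian_mean_shift_modes(table.coords, bandwidth, truncate)
    labels = _fuse_modes(modes, MS_FUSE_FRACTION * bandwidth)
    return labels_to_blobs(table, labels)


def dbscan(
    table: LocalizationTable, eps: float, min_pnts: int
) -> Tuple[List[Blob], np.ndarray]:
    """Density-reachability clustering; clusters below min_pnts are noise.

    Returns (blobs, noise_indices). Distances are Euclidean; border points
    follow scikit-learn's index-order assignment, which is deterministic.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pnts < 1:
        raise ValueError("min_pnts must be >= 1")
    if table.n == 0:
        return [], np.empty(0, dtype=int)
    labels = DBSCAN(eps=eps, min_samples=min_pnts).fit_predict(table.coords)
    # density-reachable clusters can in principle shed members below
    # min_pnts only through border sharing; enforce the size rule anyway
    for lab in np.unique(labels):
        if lab != -1 and np.sum(labels == lab) < min_pnts:
            labels[labels == lab] = -1
    blobs = labels_to_blobs(table, labels)
    return blobs, np.flatnonzero(labels == -1)


def _order_by_polar_angle(centroids: np.ndarray) -> np.ndarray:
    """Order ring centroids counter-clockwise about their in-plane center."""
    xy = centroids[:, :2]
    center = xy.mean(axis=0)
    ang = np.arctan2(xy[:, 1] - center[1], xy[:, 0] - center[0])
    return np.argsort(ang, kind="stable")


def adjacency_distances(
    blobs: Sequence[Blob],
    mode: str,
    ring_assignment: Optional[Dict[int, int]] = None,
) -> dict:
    """Centroid-distance statistics within and across octagonal rings.

    mode="adjacent_ring": consecutive centroids in polar-angle order around
    each ring (cyclic). mode="opposing_ring": centroid pairs m/2 steps apart
    in that order (4 steps for an 8-fold ring — the across-ring diameter).
    mode="inter_ring": nearest-centroid pairing between ring 1 and ring 2.

    ring_assignment maps blob id -> ring (1 or 2); by default all blobs are
    one ring. Returns mean, standard error, n and the raw distances.
    """
    if mode not in ("adjacent_ring", "opposing_ring", "inter_ring"):
        raise ValueError(f"unknown mode {mode!r}")
    if ring_assignment is None:
        ring_assignment = {b.id: 1 for b in blobs}
    rings: Dict[int, List[Blob]] = {}
    for b in blobs:
        rings.setdefault(ring_assignment[b.id], []).append(b)

    distances: List[float] = []
    if mode == "inter_ring":
        if len(rings) != 2:
            raise ValueError("inter_ring mode requires blobs in exactly 2 rings")
        (ra, rb) = (np.asarray([b.centroid for b in rings[k]])
                    for k in sorted(rings))
        if len(ra) < 1 or len(rb) < 1:
            raise ValueError("inter_ring mode requires blobs in both rings")
        tree = cKDTree(rb)
        d, _ = tree.query(ra)
        distances = list(np.atleast_1d(d))
    else:
        for _, ring_blobs in sorted(rings.items()):
            cents = np.asarray([b.centroid for b in ring_blobs])
            m = len(cents)
            if m < 2:
                continue
            order = _order_by_polar_angle(cents)
            cents = cents[order]
            if mode == "adjacent_ring":
                for k in range(m):
                    distances.append(
                        float(np.linalg.norm(cents[k] - cents[(k + 1) % m]))
                    )
            else:
                step = m // 2
                for k in range(step):
                    distances.append(
                        float(np.linalg.norm(cents[k] - cents[k + step]))
                    )
    if len(distances) < 1:
        raise ValueError(f"fewer than 2 blobs available for mode {mode!r}")
    arr = np.asarray(distances)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return {
        "mode": mode,
        "mean": float(arr.mean()),
        "sem": sem,
        "n": len(arr),
        "distances": arr,
    }
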