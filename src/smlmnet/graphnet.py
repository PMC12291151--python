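"""Proximity graphs, blink merging, Ripley's H-function and spatial nulls.

The proximity graph connects every pair of localizations whose Euclidean
distance is at most a threshold r (inclusive). Node degree in this graph is
the basic local-density statistic used for denoising, and Ripley's
H-function over a grid of radii identifies the characteristic cluster
scales (for nuclear pores: the pore scale and the corner scale) that set
the segmentation bandwidths downstream.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .locio import LocalizationTable

__all__ = [
    "ProximityGraph",
    "RipleyCurve",
    "ScaleDetection",
    "build_graph",
    "degrees",
    "merge_blinks",
    "ripley_h",
    "find_scales",
    "randomize",
]


@dataclass(frozen=True)
class ProximityGraph:
    """Undirected graph over localizations with all pairwise edges <= r.

    Edges are stored as parallel arrays ``edge_i < edge_j`` with their
    Euclidean distances; no self-loops, no duplicates.
    """

    n_nodes: int
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_dist: np.ndarray
    r: float
    dim: int

    @property
    def n_edges(self) -> int:
        return len(self.edge_i)

    def edge_pairs(self) -> np.ndarray:
        """(m, 2) array of index pairs, i < j, lexicographically sorted."""
        return np.column_stack([self.edge_i, self.edge_j])


@dataclass(frozen=True)
class RipleyCurve:
    """Ripley's H over an ascending radius grid.

    H(r) = L(r) - r with L the variance-stabilized K; expectation 0 under
    complete spatial randomness, positive at radii where points cluster.
    """

    radii: np.ndarray
    H: np.ndarray
    n: int
    region_measure: float
    dim: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_nm": self.radii, "H": self.H})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ScaleDetection:
    """Cluster scales read off a Ripley curve: argmax peak and the first
    inflection of the (smoothed) curve below the peak."""

    peak_radius: Optional[float]
    inflection_radius: Optional[float]
    has_peak: bool


def build_graph(table: LocalizationTable, r: float) -> ProximityGraph:
    """Connect every pair of localizations at Euclidean distance <= r.

    Uses a k-d tree, so fields of ~10^6 localizations are tractable as long
    as r stays at the cluster scale.
    """
    if r < 0:
        raise ValueError("proximity threshold r must be >= 0")
    n = table.n
    if n == 0:
        empty = np.empty(0)
        return ProximityGraph(0, empty.astype(int), empty.astype(int), empty,
                              float(r), table.dim)
    tree = cKDTree(table.coords)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if len(pairs):
        # enforce i < j and a deterministic lexicographic edge order
        pairs = np.sort(pairs, axis=1)
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
        dists = np.linalg.norm(
            table.coords[pairs[:, 0]] - table.coords[pairs[:, 1]], axis=1
        )
    else:
        pairs = np.empty((0, 2), dtype=int)
        dists = np.empty(0)
    return ProximityGraph(
        n_nodes=n,
        edge_i=pairs[:, 0],
        edge_j=pairs[:, 1],
        edge_dist=dists,
        r=float(r),
        dim=table.dim,
    )


def degrees(graph: ProximityGraph) -> np.ndarray:
    """Per-node degree; sums to twice the edge count."""
    deg = np.zeros(graph.n_nodes, dtype=int)
    if graph.n_edges:
        deg += np.bincount(graph.edge_i, minlength=graph.n_nodes)
        deg += np.bincount(graph.edge_j, minlength=graph.n_nodes)
    return deg


def merge_blinks(
    table: LocalizationTable, merge_threshold: float
) -> Tuple[LocalizationTable, np.ndarray]:
    """Iteratively merge localizations closer than a merge threshold.

    Repeatedly replaces the closest pair at distance <= threshold by its
    unweighted centroid until no pair is closer than the threshold,
    collapsing the multiple-blink clusters one fluorophore leaves behind.
    Ties on distance are broken by the smallest index pair, which makes
    the iteration deterministic.

    Returns the merged table and a ``merge_map`` sending each input row to
    its output row.
    """
    if merge_threshold < 0:
        raise ValueError("merge_threshold must be >= 0")
    n = table.n
    if merge_threshold == 0 or n < 2:
        return table, np.arange(n)

    coords = [table.coords[i].copy() for i in range(n)]
    alive = [True] * n
    parent = list(range(n))  # union-find over merge events

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    heap: list[tuple[float, int, int]] = []
    tree = cKDTree(table.coords)
    for i, j in tree.query_pairs(merge_threshold, output_type="ndarray"):
        a, b = (int(i), int(j)) if i < j else (int(j), int(i))
        d = float(np.linalg.norm(table.coords[a] - table.coords[b]))
        heapq.heappush(heap, (d, a, b))

    while heap:
        d, a, b = heapq.heappop(heap)
        if not (alive[a] and alive[b]):
            continue
        centroid = (coords[a] + coords[b]) / 2.0
        alive[a] = alive[b] = False
        k = len(coords)
        coords.append(centroid)
        alive.append(True)
        parent.append(k)
        parent[a] = parent[b] = k
        alive_idx = [m for m in range(k) if alive[m]]
        if alive_idx:
            pts = np.asarray([coords[m] for m in alive_idx])
            dists = np.linalg.norm(pts - centroid, axis=1)
            for m, dm in zip(alive_idx, dists):
                if dm <= merge_threshold:
                    heapq.heappush(heap, (float(dm), m, k))

    final_nodes = sorted(m for m in range(len(coords)) if alive[m])
    out_index = {node: rank for rank, node in enumerate(final_nodes)}
    merge_map = np.array([out_index[find(i)] for i in range(n)], dtype=int)
    merged = LocalizationTable(
        coords=np.asarray([coords[m] for m in final_nodes]), roi=table.roi
    )
    return merged, merge_map


def ripley_h(table: LocalizationTable, radii) -> RipleyCurve:
    """Ripley's H-function of the table over an ascending radius grid.

    K(r) = measure / (n (n-1)) * #{ordered pairs i != j with d_ij <= r};
    L(r) = sqrt(K/pi) in 2D or (3K/(4 pi))^(1/3) in 3D; H(r) = L(r) - r.
    No edge correction is applied — ROIs are assumed large relative to the
    radii of interest, leaving a small negative bias near borders.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or len(radii) == 0:
        raise ValueError("radii must be a non-empty 1D array")
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    n = table.n
    if n < 2:
        raise ValueError("insufficient points: Ripley's H requires n >= 2")
    measure = table.roi_measure()
    if measure <= 0:
        raise ValueError("ROI measure must be positive")

    tree = cKDTree(table.coords)
    # count_neighbors over the full grid counts ordered pairs incl. self-pairs
    counts = tree.count_neighbors(tree, radii).astype(float) - n
    K = measure * counts / (n * (n - 1))
    if table.dim == 2:
        L = np.sqrt(K / np.pi)
    else:
        L = np.cbrt(3.0 * K / (4.0 * np.pi))
    return RipleyCurve(radii=radii, H=L - radii, n=n,
                       region_measure=measure, dim=table.dim)


def _smooth3(y: np.ndarray) -> np.ndarray:
    """Centered moving average, window 3, ends copied through."""
    if len(y) < 3:
        return y.copy()
    s = y.copy()
    s[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return s


def find_scales(curve: RipleyCurve) -> ScaleDetection:
    """Identify the cluster-scale peak and the sub-cluster inflection of H.

    The peak is the argmax of H, which must be interior to the grid; the
    inflection is the first radius below the peak where the second
    difference of the window-3 smoothed curve changes sign.
    """
    H, radii = curve.H, curve.radii
    if len(radii) < 5:
        raise ValueError("find_scales requires at least 5 curve samples")
    k = int(np.argmax(H))
    if k == 0 or k == len(H) - 1:
        return ScaleDetection(None, None, has_peak=False)
    peak_radius = float(radii[k])

    s = _smooth3(H)
    d2 = np.diff(s, 2)  # d2[i] ~ curvature at grid point i+1
    inflection = None
    sign = np.sign(d2)
    for i in range(1, min(k, len(d2))):
        if sign[i] != 0 and sign[i - 1] != 0 and sign[i] != sign[i - 1]:
            inflection = float(radii[i + 1])
            break
    return ScaleDetection(peak_radius, inflection, has_peak=True)


def randomize(table: LocalizationTable, seed: int) -> LocalizationTable:
    """Uniformly re-scatter the same number of points over the ROI box.

    This is the complete-spatial-randomness null used to calibrate the
    degree filter: same n, same region, no structure.
    """
    roi = table.roi
    if roi is None:
        raise ValueError("randomize requires the table ROI to be set")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(roi[:, 0], roi[:, 1], size=(table.n, table.dim))
    return LocalizationTable(coords=coords, roi=roi)
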