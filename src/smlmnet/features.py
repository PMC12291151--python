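"""Per-blob quantification: 30 size/shape/hollowness/statistical/network
features, plus shrink-factor boundaries.

The feature vector mixes geometry (extents, hulls, radius of gyration,
distance statistics), shape from covariance eigenvalues, hollowness (rings
score higher than filled disks), and graph statistics of the blob-internal
proximity network (degree, density, path length, clustering, modularity,
assortativity). Fixed column order; 2D blobs report z_range = 0 and
planarity = 0 so the matrix width never changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .graphnet import ProximityGraph, build_graph, degrees
from .locio import LocalizationTable
from .modules import greedy_newman
from .segment import Blob

__all__ = [
    "FEATURE_NAMES",
    "Boundary",
    "DegenerateGeometryError",
    "boundary",
    "compute_features",
    "feature_matrix",
    "characteristic_path",
    "feature_histograms",
]

#: fixed, documented column order of the feature matrix
FEATURE_NAMES: Tuple[str, ...] = (
    "n_locs",
    "x_range", "y_range", "z_range",
    "hull_measure",        # convex-hull area (2D, nm^2) or volume (3D, nm^3)
    "hull_boundary",       # hull perimeter (2D, nm) or surface area (3D, nm^2)
    "radius_of_gyration",
    "dist_centroid_min", "dist_centroid_max", "dist_centroid_mean",
    "dist_centroid_median", "dist_centroid_sd",
    "pair_dist_min", "pair_dist_max", "pair_dist_mean",
    "pair_dist_median", "pair_dist_sd",
    "pca_anisotropy", "pca_linearity", "pca_planarity",
    "hollowness",
    "mean_degree", "degree_sd", "network_density",
    "characteristic_path", "clustering_coefficient",
    "modularity_Q", "n_modules", "n_components", "assortativity",
)


class DegenerateGeometryError(ValueError):
    """Point set has no full-dimensional hull (collinear/coplanar/too few)."""


@dataclass(frozen=True)
class Boundary:
    """A shrink-factor boundary around a point set.

    shrink = 0 is the convex hull; shrink = 1 the tightest single connected
    alpha complex that still contains every point; intermediate values
    interpolate the circumradius cutoff monotonically.
    """

    shrink: float
    simplices: np.ndarray       # kept Delaunay simplices, (k, d+1) indices
    boundary_facets: np.ndarray  # facets on the boundary, (f, d) indices
    measure: float              # enclosed area (2D) or volume (3D)
    boundary_measure: float     # perimeter (2D) or surface area (3D)


def _simplex_measure(pts: np.ndarray) -> float:
    """Area of a triangle / volume of a tetrahedron from vertex coords."""
    v = pts[1:] - pts[0]
    d = pts.shape[1]
    if d == 2:
        return abs(np.linalg.det(v)) / 2.0
    return abs(np.linalg.det(v)) / 6.0


def _circumradius(pts: np.ndarray) -> float:
    """Circumradius of a d-simplex (triangle in 2D, tetrahedron in 3D)."""
    p0 = pts[0]
    A = 2.0 * (pts[1:] - p0)
    # circumcenter c solves 2(p_i - p0).c = |p_i|^2 - |p0|^2 for all i
    b = np.einsum("ij,ij->i", pts[1:] - p0, pts[1:] + p0)
    try:
        c = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    return float(np.linalg.norm(c - p0))


def _facet_measure(pts: np.ndarray) -> float:
    """Length of a 2D edge / area of a 3D triangle facet."""
    if len(pts) == 2:
        return float(np.linalg.norm(pts[1] - pts[0]))
    return float(np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0])) / 2)


def _complex_stats(points: np.ndarray, simplices: np.ndarray):
    """Measure, boundary facets and boundary measure of a simplicial complex."""
    from collections import Counter

    measure = float(sum(_simplex_measure(points[s]) for s in simplices))
    facet_count: Counter = Counter()
    d1 = simplices.shape[1]
    for s in simplices:
        for drop in range(d1):
            facet = tuple(sorted(np.delete(s, drop)))
            facet_count[facet] += 1
    boundary_facets = np.asarray(
        [f for f, c in facet_count.items() if c == 1], dtype=int
    ).reshape(-1, d1 - 1)
    bmeasure = float(sum(_facet_measure(points[list(f)])
                         for f in boundary_facets))
    return measure, boundary_facets, bmeasure


def _complex_ok(simplices: np.ndarray, n_points: int) -> bool:
    """Kept complex must be a single connected shape containing all points."""
    if len(simplices) == 0:
        return False
    used = np.unique(simplices)
    if len(used) != n_points:
        return False
    # connectivity via shared vertices
    idx = {v: k for k, v in enumerate(used)}
    rows, cols = [], []
    for si, s in enumerate(simplices):
        for v in s:
            rows.append(si)
            cols.append(idx[v])
    inc = csr_matrix((np.ones(len(rows)), (rows, cols)),
                     shape=(len(simplices), len(used)))
    adj = (inc @ inc.T) > 0
    ncomp, _ = connected_components(adj, directed=False)
    return ncomp == 1


def boundary(points: np.ndarray, shrink: float) -> Boundary:
    """Shrink-factor boundary of a blob's point set.

    Built from the Delaunay triangulation by discarding simplices with a
    circumradius above a cutoff. shrink = 0 keeps everything (the convex
    hull); shrink = 1 lowers the cutoff to the smallest value at which the
    complex is still one connected piece containing all the points; values
    in between interpolate the cutoff rank linearly.
    """
    if not 0.0 <= shrink <= 1.0:
        raise ValueError("shrink must lie in [0, 1]")
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    if n < d + 1:
        raise DegenerateGeometryError(
            f"boundary needs at least {d + 1} points in {d}D"
        )
    try:
        tri = Delaunay(points)
    except QhullError as err:
        raise DegenerateGeometryError(f"degenerate point set: {err}") from err
    simplices = tri.simplices
    radii = np.asarray([_circumradius(points[s]) for s in simplices])
    order = np.argsort(radii)[::-1]  # drop largest-circumradius first

    # find how many of the largest simplices can be dropped before the
    # complex disconnects or loses a point: that prefix defines shrink=1
    max_drop = 0
    for drop in range(1, len(simplices)):
        kept = simplices[order[drop:]]
        if _complex_ok(kept, n):
            max_drop = drop
        else:
            break
    n_drop = int(round(shrink * max_drop))
    kept = simplices[order[n_drop:]]
    measure, facets, bmeasure = _complex_stats(points, kept)
    return Boundary(
        shrink=float(shrink),
        simplices=kept,
        boundary_facets=facets,
        measure=measure,
        boundary_measure=bmeasure,
    )


def characteristic_path(graph: ProximityGraph) -> float:
    """Mean shortest-path length in hops over connected node pairs.

    Pairs in different components are excluded; a graph with no connected
    pair has characteristic path 0.
    """
    n = graph.n_nodes
    if n < 2 or graph.n_edges == 0:
        return 0.0
    data = np.ones(graph.n_edges)
    adj = csr_matrix((data, (graph.edge_i, graph.edge_j)), shape=(n, n))
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    iu = np.triu_indices(n, 1)
    vals = dist[iu]
    finite = vals[np.isfinite(vals)]
    if len(finite) == 0:
        return 0.0
    return float(finite.mean())


def _network_features(pts: np.ndarray, graph: ProximityGraph) -> dict:
    n = graph.n_nodes
    if n < 2:
        return {k: 0.0 for k in ("mean_degree", "degree_sd", "network_density",
                                 "characteristic_path", "clustering_coefficient",
                                 "modularity_Q", "n_modules", "n_components",
                                 "assortativity")}
    deg = degrees(graph)
    density = 2.0 * graph.n_edges / (n * (n - 1))
    edges = list(zip(graph.edge_i.tolist(), graph.edge_j.tolist()))
    labels, Q = greedy_newman(n, edges)

    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(edges)
    clustering = nx.average_clustering(G) if graph.n_edges else 0.0
    n_components = nx.number_connected_components(G)
    if graph.n_edges:
        with np.errstate(invalid="ignore", divide="ignore"):
            assort = nx.degree_assortativity_coefficient(G)
        if not np.isfinite(assort):
            assort = 0.0  # regular graphs: correlation undefined
    else:
        assort = 0.0
    return {
        "mean_degree": float(deg.mean()),
        "degree_sd": float(deg.std()),
        "network_density": float(density),
        "characteristic_path": characteristic_path(graph),
        "clustering_coefficient": float(clustering),
        "modularity_Q": float(Q),
        "n_modules": float(labels.max() + 1),
        "n_components": float(n_components),
        "assortativity": float(assort),
    }


def compute_features(blob: Blob, table: LocalizationTable,
                     network_r: float) -> np.ndarray:
    """The 30-feature vector of one blob, in FEATURE_NAMES order.

    network_r is the proximity threshold of the blob-internal graph used
    for the network features (the sub-cluster scale by default in the
    pipeline). Single-point blobs report zero for every distance and
    network feature; degenerate hulls report measure 0.
    """
    pts = table.coords[blob.members]
    n, d = pts.shape
    f = dict.fromkeys(FEATURE_NAMES, 0.0)
    f["n_locs"] = float(n)
    rng = pts.max(axis=0) - pts.min(axis=0) if n else np.zeros(d)
    f["x_range"], f["y_range"] = float(rng[0]), float(rng[1])
    f["z_range"] = float(rng[2]) if d == 3 else 0.0

    try:
        hull = ConvexHull(pts)
        f["hull_measure"] = float(hull.volume)  # area in 2D
        f["hull_boundary"] = float(hull.area)   # perimeter in 2D
    except (QhullError, ValueError):
        pass  # degenerate: stays 0

    centroid = pts.mean(axis=0)
    dc = np.linalg.norm(pts - centroid, axis=1)
    f["radius_of_gyration"] = float(np.sqrt(np.mean(dc ** 2)))
    if n >= 2:
        f["dist_centroid_min"] = float(dc.min())
        f["dist_centroid_max"] = float(dc.max())
        f["dist_centroid_mean"] = float(dc.mean())
        f["dist_centroid_median"] = float(np.median(dc))
        f["dist_centroid_sd"] = float(dc.std())
        iu = np.triu_indices(n, 1)
        pd = np.linalg.norm(pts[iu[0]] - pts[iu[1]], axis=1)
        f["pair_dist_min"] = float(pd.min())
        f["pair_dist_max"] = float(pd.max())
        f["pair_dist_mean"] = float(pd.mean())
        f["pair_dist_median"] = float(np.median(pd))
        f["pair_dist_sd"] = float(pd.std())
        if dc.max() > 0:
            f["hollowness"] = float(dc.mean() / dc.max())

        cov = np.cov(pts, rowvar=False, ddof=0)
        ev = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
        ev = np.clip(ev, 0.0, None)
        if ev[0] > 0:
            f["pca_anisotropy"] = float(1.0 - ev[-1] / ev[0])
            f["pca_linearity"] = float((ev[0] - ev[1]) / ev[0])
            if d == 3:
                f["pca_planarity"] = float((ev[1] - ev[2]) / ev[0])

        sub = LocalizationTable(coords=pts)
        f.update(_network_features(pts, build_graph(sub, network_r)))
    return np.asarray([f[name] for name in FEATURE_NAMES])


def feature_matrix(blobs: Sequence[Blob], table: LocalizationTable,
                   network_r: float) -> Tuple[np.ndarray, List[str]]:
    """Stack per-blob feature vectors into an (n_blobs, 30) matrix."""
    if len(blobs) == 0:
        return np.empty((0, len(FEATURE_NAMES))), list(FEATURE_NAMES)
    rows = [compute_features(b, table, network_r) for b in blobs]
    return np.vstack(rows), list(FEATURE_NAMES)


def feature_histograms(matrix: np.ndarray, n_bins: int = 30):
    """Per-feature histograms (bin edges, counts) for export."""
    out = {}
    for k, name in enumerate(FEATURE_NAMES):
        col = matrix[:, k]
        counts, edges = np.histogram(col, bins=n_bins)
        out[name] = (edges, counts)
    return out
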