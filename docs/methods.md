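# Methods

This note documents the models, estimators and numerical choices behind
`smlmnet`, what the synthetic generator does and does not emulate, and the
known limitations.

## Data model and conventions

A localization table holds one row per detected blink with coordinates in
nanometres (2D or 3D). Readers convert pixel inputs with an explicit pixel
size; the internal unit is always nm. Input row order is preserved and
used as the stable localization index by every downstream module. The ROI
is an axis-aligned box, defaulting to the data bounding box; ROI cropping
uses half-open intervals [min, max) per axis so boundary membership is
deterministic.

## Proximity graph

Nodes are localizations; the pair (i, j) is an edge iff the Euclidean
distance d_ij ≤ r (inclusive — ties at exactly r are edges). Graphs are
built with a k-d tree, never an all-pairs scan, so 10^6-localization
fields stay tractable at cluster-scale r. Degree (edge count per node) is
the local density statistic used throughout.

## Blink merging

One fluorophore can blink several times, leaving a local cluster of
localizations. The merge step repeatedly finds the closest pair at
distance ≤ the merge threshold and replaces it with its unweighted
centroid until no pair remains below threshold. Closest-pair-first order
with smallest-index tie-breaks makes the iteration deterministic; the
output is guaranteed to have no pair closer than the threshold, and
re-running is a no-op. Precision-weighted averaging is deliberately not
the default (the merge target is an estimated average location).
Temporal (frame-gap) merging is out of scope: the public nuclear-pore
reference datasets arrive temporally pre-merged, which is also why the
pipeline's merge stage defaults to off.

## Ripley's H-function

K(r) = |A| / (n(n−1)) · Σ_{i≠j} 1[d_ij ≤ r], with |A| the ROI measure;
L(r) = √(K/π) (2D) or (3K/4π)^{1/3} (3D); H(r) = L(r) − r. The n(n−1)
normalization makes K unbiased under CSR. No edge correction is applied:
ROIs are assumed large relative to the radii of interest, which leaves a
small negative bias near borders (for a 5 µm box at r = 50 nm the bias is
a fraction of a nm, well inside the Monte-Carlo error of the CSR tests).

Scale detection takes the argmax of H as the cluster-scale peak (flagged
absent if it falls on a grid endpoint) and, below the peak, the first sign
change of the second difference of the window-3 moving-average-smoothed
curve as the sub-cluster inflection. Smoothing window and differencing
scheme are artifact choices; the peak/inflection radii are meant to be
read at the grid resolution, not sub-grid.

## Degree-based denoising

The null is the same number of points scattered i.i.d. uniformly over the
ROI box (box rather than convex hull: deterministic and cheap). The keep
rule is degree ≥ α × (mean degree of one randomized realization under the
given seed); equality is kept. Averaging over k > 1 realizations is
available but defaults to 1. A manual threshold override stands in for
calibration against a structure-free background area. The keep set is
nested in α (larger α never keeps a localization that a smaller α
removed), and filtering never alters surviving coordinates.

## Segmentation

Mean-shift uses a Gaussian kernel with bandwidth h interpreted as the
kernel standard deviation. Every localization is iterated by
m(x) = Σ_i w_i x_i / Σ_i w_i, w_i = exp(−‖x − x_i‖²/2h²), until the
displacement falls below 0.01 nm or 300 iterations; modes within h/2 are
fused into one blob. For speed the kernel is truncated at 3h using a k-d
tree; the truncated and full-kernel assignments agree on test fixtures.
Convergence tolerance, iteration cap and fusion radius are artifact
decisions. Blob labels are assigned by smallest member index, making the
segmentation invariant to input row order up to relabelling. Bandwidth
acts as expected: too large under-segments (fuses neighbours), too small
over-segments; the blob count is non-increasing in h on the tested grids.

DBSCAN wraps scikit-learn (Euclidean metric) with a post-filter that
demotes clusters smaller than MinPnts to noise; border-point assignment
follows scikit-learn's deterministic index-order scan.

Ring-geometry statistics order corner centroids by polar angle about the
per-ring center: adjacent = consecutive pairs (cyclic), opposing = pairs
m/2 steps apart (4 for an 8-fold ring), inter-ring = nearest-centroid
pairing across the two rings. For 3D double rings, ring membership is
assigned by the sign of z relative to the global z-median.

## Blob features

30 features per blob, fixed column order (`smlmnet.FEATURE_NAMES`):
localization count; x/y/z ranges (z_range = 0 in 2D); convex-hull measure
and boundary (area/perimeter in 2D, volume/surface in 3D); radius of
gyration √(mean ‖x_i − c‖²); min/max/mean/median/sd of distance to
centroid and of all pairwise distances; covariance-eigenvalue shape
scores anisotropy = 1 − λ_d/λ_1, linearity = (λ_1 − λ_2)/λ_1, planarity =
(λ_2 − λ_3)/λ_1 (0 in 2D); hollowness = mean/max distance to centroid
(≈ 2/3 for a uniform disk, → 1 for a thin ring); and, on the
blob-internal proximity graph at a user-set network radius (default: the
sub-cluster scale used for filtering): mean degree, degree sd, density
2|E|/n(n−1), characteristic path (mean hop count over connected pairs, 0
if none), average clustering coefficient, greedy-Newman modularity Q and
module count, connected-component count, and degree assortativity (0 when
undefined, e.g. regular graphs). Single-point blobs report 0 for all
distance and network features; degenerate hulls report measure 0.

These definitions reproduce the documented qualitative contrasts (hollow
ring-like blobs score higher hollowness than compact ones; small isolated
clusters show higher density and lower modularity than full rings), but
exact numeric parity with any other tool's feature values is not claimed.

The shrink-factor boundary is built on the Delaunay triangulation:
simplices are discarded in descending circumradius order. Shrink 0 keeps
everything (the convex hull); shrink 1 drops the longest prefix that
leaves a single connected complex containing every point; intermediate
values interpolate the drop count linearly. Enclosed measure is therefore
monotone non-increasing in shrink and maximal at the convex hull.

## Grouping and retrieval

Features are column z-scored with the population (n-denominator) sd;
zero-variance columns become all-zero and are flagged (they then carry no
weight in any Euclidean computation). K-means uses k-means++ with 10
restarts and a mandatory seed; K is user-chosen (typically from bimodal
feature histograms), and groups are relabelled 1..K by descending size.
Silhouette (Euclidean) assesses grouping quality. Group similarity is the
Euclidean distance between group mean vectors in normalized space.
Representative retrieval sorts a group's blobs by distance to the group
mean, ties broken by blob id.

## Modularity analysis

Per blob, the internal proximity graph at a modularity threshold is
partitioned by greedy agglomerative (fast-greedy) maximization of
Q = Σ_c (e_cc − a_c²): starting from singletons, the community pair with
the largest ΔQ = e_12 − 2 a_1 a_2 is merged until no merge is positive.
ΔQ ties are broken by the smallest community-id pair, and community ids
are the smallest member node index, so the partition is independent of
node order. Disconnected components never merge (their ΔQ is negative),
so they are always separate modules. On the ≤ 8-node graphs in the test
suite the greedy optimum matches exhaustive partition search; where
greedy can be suboptimal on larger graphs, Q_greedy ≤ Q_exhaustive holds
by construction. Module centroids are unweighted member means.

The 2-module analysis: sweeping the threshold (6–20 nm for corner-scale
blobs) and counting blobs with exactly 2 modules peaks near the scale of
the underlying molecular pair. Blobs with few localizations yield erratic
inter-centroid distances, so the index of dispersion (variance/mean,
sample variance, ddof = 1) of the distance is computed per integer
localization-count bin (bins with < 2 blobs are dropped), fitted with an
order-5 polynomial, and the first sign change of the fitted second
derivative (evaluated analytically on a 0.01-step grid over the data
range) gives the minimum localization count for reliable distances. The
final estimate is the mean ± SEM (ddof = 1) inter-centroid distance over
qualifying 2-module blobs.

## Synthetic generator

`simulate_npc_field` emulates the features of nuclear-pore SMLM data that
the analysis depends on: octagonal rings (default ring diameter 107 nm,
giving 42 nm adjacent- and 107 nm opposing-corner spacing, the `nup96_2d`
preset; a 3D double-ring preset `nup107_3d` uses 37.4 nm adjacent spacing
and 58.7 nm axial ring separation), 2 molecules per corner 12 nm apart
along the local ring tangent, per-pore uniform random rotation, Poisson-
distributed blink counts per labeled molecule (default mean 6; zero-blink
molecules model incomplete detection on top of the labeling efficiency),
isotropic Gaussian localization noise (default sd 4 nm), and uniform
background. Pore centers are rejection-sampled with a minimum separation
that guarantees non-overlapping rings. `simulate_corners` places isolated
molecule pairs on a sparse grid for modularity-focused tests, and
`simulate_csr` provides the uniform null.

The generator does **not** emulate frame-level photophysics (on/off
kinetics, photon counts, PSF fitting), drift, repeated-frame artifacts, or
antibody-linkage error; blink counts are Poisson as a modeling choice
(real blink-count laws are dataset-specific). Passing recovery tests
therefore shows the analysis chain is correct under the stated geometric
and noise assumptions — not that any particular real dataset meets them.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale simulations
chosen to give tight Monte-Carlo error at interactive runtimes: 20 CSR
fields of 5000 points for the Ripley null, 100-pore fields for geometry
recovery, 500 corners for the molecular-spacing recovery. All randomness
flows through explicit integer seeds (numpy `default_rng`); identical
configs and seeds reproduce byte-identical pipeline outputs.

## Known limitations

- Ripley's K has no edge correction (small negative border bias).
- The greedy modularity optimum is not guaranteed globally optimal on
  large, dense blob graphs.
- The iterative closest-pair merge is O(n·m) in the worst case and is
  intended for blob-scale or pre-thinned data, not multi-million-event
  merging.
- Mean-shift mode fusion at h/2 is a heuristic; structures separated by
  less than the fusion radius merge into one blob.
- Feature definitions are this package's own (documented above); they
  preserve ranks and contrasts rather than matching any external tool
  digit for digit.
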