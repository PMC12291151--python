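# smlmnet

Network analysis of single-molecule localization microscopy (SMLM) point
clouds. `smlmnet` takes a raw localization table (one row per detected
blink, coordinates in nm) and turns it into quantified biological
structures: it merges multiple-blink artifacts, finds the characteristic
cluster scales with Ripley's H-function, removes background by comparing
node degrees against a randomized network, segments clusters ("blobs")
with mean-shift or DBSCAN, extracts 30 size/shape/hollowness/network
features per blob, groups blobs by K-means, retrieves representative
blobs, and decomposes individual blobs into Newman-modularity communities
("modules") whose centroid distances report molecular spacings below the
nominal localization precision.

The package is aimed at microscopists and image analysts working with
dSTORM / PALM / PAINT localization lists, and at method developers who
need a ground-truthed synthetic nuclear-pore simulator to validate cluster
analysis.

## The analysis in brief

Localizations are nodes; any pair within a proximity threshold *r* is an
edge. Three graph-based statistics drive the pipeline:

- **Ripley's H**: H(r) = L(r) − r with L(r) = √(K(r)/π) in 2D and
  K(r) = |A| / (n(n−1)) · Σ_{i≠j} 1[d_ij ≤ r]. E[H] = 0 under complete
  spatial randomness; peaks mark cluster scales (for nuclear pores: the
  pore scale ~118 nm and the corner scale ~12 nm).
- **Degree filtering**: a CSR field with the same n and region is
  generated; localizations with degree < α × (mean degree of the random
  network) at the sub-cluster radius are removed as background.
- **Newman modularity**: within one segmented blob, the proximity graph at
  a small threshold is partitioned by greedy agglomerative maximization of
  Q = Σ_c (e_cc − a_c²). Each module is interpreted as the blink cluster
  of one underlying molecule, so inter-module centroid distances measure
  molecular spacings. On nuclear-pore corners (two nucleoporin copies
  ~12 nm apart) this attains molecular resolution from conventional
  dSTORM-scale data.

Mean-shift segmentation uses a Gaussian kernel whose bandwidth h is the
expected cluster standard deviation; blob features, K-means grouping (on
column z-scored features), silhouette quality and representative-blob
retrieval follow. See `docs/methods.md` for definitions, parameter
defaults and limitations.

## Worked example

Simulate a field of 50 nuclear-pore-like structures (8 corners on a ring
of diameter 107 nm, 2 molecules per corner 12 nm apart, Poisson(6) blinks
per molecule, 4 nm localization noise), then recover the molecular spacing:

```sh
smlmnet simulate npc --preset nup96_2d --pores 50 --seed 1 \
    --out locs.csv --truth truth.csv
# {"n_localizations": 4863}

smlmnet ripley locs.csv --rmin 6 --rmax 200 --step 2 --out ripley.csv
# {"peak_radius_nm": 114.0, "inflection_radius_nm": 24.0, "has_peak": true}

smlmnet segment meanshift locs.csv --bandwidth 12 --out corners.csv
# {"n_blobs": 392}

smlmnet modules summary locs.csv corners.csv --r 10 --minlocs 11
# {"mean_distance_nm": 12.091129531657064, "sem_nm": 0.1493931604154969,
#  "n_blobs_used": 196}
```

The H-function peak near 114 nm reflects the pore scale of the simulated
field. Corner-scale mean-shift (bandwidth 12 nm) segments ~8 corner blobs
per pore; modularity analysis at threshold 10 nm over blobs with at least
11 localizations finds two modules per corner whose centroids sit
12.09 ± 0.15 nm apart — recovering the generator's 12 nm molecule spacing
from blink clusters whose localization noise (4 nm sd) is of the same
order as the spacing.

The same stages are available as library calls
(`smlmnet.simulate_npc_field`, `smlmnet.mean_shift`,
`smlmnet.two_module_summary`, ...), and `smlmnet run config.txt` chains
them from a flat key=value config file with fixed seeds and per-stage CSV
outputs.

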