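# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make runs reproducible across
platforms.

## Occurrence cleaning

Four rules run in a fixed order — exact duplicates → coordinate precision →
nodata location → altitude envelope — and each drop is attributed to the
first rule that catches it, so the audit counts always reconcile with the
input size. Choices that the workflow leaves open and how they are resolved
here:

- *Duplicates* are exact string-normalized (species, longitude, latitude)
  triples, not a distance tolerance: deterministic, and it is what
  "repeated records" means in passport data assembled from multiple
  repositories. First occurrence wins.
- *Low precision* counts written decimal digits (the raw CSV token is kept
  on the record for this purpose; a parsed float cannot recover it).
  Default `min_decimals = 2`, about 1.1 km at the equator — the same order
  as a 900 m environmental layer, so coarser coordinates cannot be assigned
  a meaningful cell. Configurable.
- *Altitude envelope*: per-species (min, max) in metres, shipped as package
  defaults for the sixteen wild-tomato-group taxa (e.g. *S. sitiens*
  2,276–3,330 m; *S. chilense* 0–3,995 m) and overridable. The altitude at
  a point is the value of the cell containing it, consistent with
  extraction everywhere else.

Output is sorted (species, record id), which makes cleaning idempotent and
independent of input order.

## Raster model and extraction

Grids are single-band, WGS84 decimal degrees, row-major with cell (0, 0) at
the northwest corner. A point belongs to the cell with half-open intervals
`[west, west + cell)` × `(north − cell, north]`; the north and west edges
belong to the first row/column, the east and south extents are exclusive.
Extraction is containing-cell only — no bilinear interpolation — because the
same rule must serve categorical class layers, and point-in-pixel lookup is
the standard GIS behaviour for both. Missing (nodata or out of extent) is a
value, not an error; any row of the environmental matrix with a missing
entry is excluded from downstream statistics and logged (complete-case
analysis).

I/O: ESRI ASCII grid (`.asc`) with `repr`-formatted floats so a write→read
round trip is bit-exact, and single-band GeoTIFF through tifffile with the
ModelPixelScale, ModelTiepoint and GDAL_NODATA tags (float32 payload).

## Collinearity screen

Greedy elimination on the Pearson matrix: while any off-diagonal |r|
exceeds the threshold (default 0.90), take the largest-|r| pair and
*conserve* the member with the greater number of |r| > threshold partners
among still-retained variables; eliminate the other. Ties fall back to the
larger sum of |r| against retained variables, then to input column order.
The conserve-the-hub reading keeps one representative of each redundant
cluster and therefore eliminates the most variables; the opposite reading
(drop the hub) is available via `conserve_hub=False`, and every step is
logged with tie flags so either trace can be audited. The elimination order
(descending |r|) is a package choice; no order is canonical.

## Canonical correlation analysis

Correlation-based CCA (each variable standardized to mean 0, sd 1 with
ddof = 1): canonical correlations are the singular values of
K = R_xx^(−1/2) R_xy R_yy^(−1/2), with symmetric inverse square roots from
eigendecompositions floored at 1e−10. A numerically singular block without
an explicit ridge is a hard error advising one, rather than a silent
pseudo-inverse: rank deficiency usually means the screen was skipped.

- *Explained-variation percentages* use the eigenvalue convention
  λ_k = r_k²/(1−r_k²), p_k = 100·λ_k/Σλ. The alternative (share of squared
  correlations) is not used; the eigenvalue convention is the one
  consistent with reported triples of the form (0.800, 0.436, 0.415) →
  (71.45, 9.38, 8.36)% , whose p₃/p₂ ratio it reproduces within print
  rounding.
- *Sequential tests*: Wilks Λ_k = Π_{i≥k}(1−r_i²) with Bartlett's χ²
  approximation −(n−1−(p+q+1)/2)·ln Λ_k on (p−k+1)(q−k+1) degrees of
  freedom. Rao's F is a common software default for the same hypothesis;
  Bartlett is used here for its closed form and is calibrated by simulation
  in the test suite (type-I error at α = 0.05 inside the exact binomial 99%
  envelope over 500 null replicates).
- *Sign convention*: each X variate is oriented so its largest-|loading|
  variable loads positively, and the paired Y variate follows so the pair
  correlates nonnegatively. Orienting both blocks independently could flip
  the sign of the pair correlation, so the Y rule is subordinated — this
  keeps r_k ≥ 0 and removes LAPACK sign indeterminacy across platforms.
- Loadings are sample correlations of the (standardized) variables with
  their own block's canonical scores; cross-loadings with the opposite
  block's scores, which equal r_k × loading on the same sample (asserted in
  tests to 1e−10).

## Ecological descriptors

Per species × variable over that species' complete-case rows: min, max,
median, quartiles, and CV = (Q/Med)·100 with Q = (Q3−Q1)/2. The quartile
estimator is linear interpolation at 0.25/0.5/0.75·(n−1) (numpy's default);
other standard sample-quantile types can be selected and the choice is
recorded in the output. Cells with median 0 (e.g. driest-month
precipitation for desert taxa) report CV = 0 with an explicit
`zero_median_flag` instead of an infinity — matching how such cells are
conventionally printed while keeping the degeneracy visible.

## Edaphoclimatic diversity

Each accession takes the class of its containing cell; counts and
within-row percentages are tabulated per species and per phylogenetic
group, with nodata-excluded records counted separately so row totals always
reconcile. Richness is the number of classes with nonzero count. The
Köppen–Geiger (30 codes) and FAO soil-unit (28 codes) vocabularies ship as
package constants; codes outside the dictionary are tolerated as
`UNKNOWN_<code>` because synthetic layers use subsets. The group-level
table is exactly the species-level table aggregated through the six-group
species map (tested, not assumed).

## Hot spots

Points are projected to a spherical azimuthal-equidistant plane anchored at
their centroid (closed-form forward/inverse, R = 6371.0088 km), snapped to
a fixed `bin_km` square grid (default 1 km), and aggregated to accession
counts (or distinct-species richness via a flag; both readings of
"abundance and diversity" are supported, count being the default). Grid
binning was chosen over order-dependent agglomerative merging for
reproducibility: the binning is a pure function of the point set.

Gi* follows the 1995 Getis–Ord form with the focal bin included
(w_ii = 1): z_i = [Σ_j w_ij x_j − X̄ S1_i] / [S·√((n·S2_i − S1_i²)/(n−1))]
over the full set of occupied bins, with binary band-distance weights.
X̄ and S are the global mean and population standard deviation. Zero global
variance, or a neighborhood covering the whole study set, defines z = 0.
The band distance is not dictated by the 1-km aggregation distance; the
default is 50 km (configurable, recorded in output metadata) — wide enough
to give Andean-valley-scale neighborhoods at the density of the emulated
dataset. No multiplicity correction is applied to the z map by default, as
hot-spot maps conventionally report raw z classes (±1.65/1.96/2.58).

## Synthetic data: what it emulates, and what it does not

- `planted_cca_sample` plants population canonical correlations exactly, by
  construction (shared latents, then within-block invertible mixing, to
  which CCA is invariant). Defaults ρ = (0.8, 0.4, 0.2) match the planted
  study conditions used throughout the tests.
- `synthetic_landscape` builds 19 continuous layers on a 200×200 grid over
  a 13°×13° Andean-coastal window (~0.065° cells): moisture-side climate
  layers and the soil physico-chemistry layers are affine in one shared
  smooth humidity field (sign-flipped for BD/pH/BS: wetter → more leached,
  acid, low-base soils), thermal layers in an independent thermal field,
  plus per-cell white noise; altitude is a monotone west→east gradient
  (0–4,500 m) used by the cleaning filter. The planted climate–soil
  leading canonical correlation is *computed over all grid cells* at
  generation time and stored in the truth ledger, since clustered sampling
  sees a range-restricted version of it.
- `synthetic_occurrences` draws Gaussian clusters (default 200 points per
  species, 30 km dispersion, km→degrees via the local-latitude cosine)
  around niche centers placed on the altitude gradient so each species'
  envelope is satisfiable, then appends planted defects that each trip
  exactly one cleaning rule; the ledger records every planted count.
- `categorical_layer` thresholds a smooth field at rank boundaries, giving
  *exact* cell-count class proportions.

Not emulated: spatial autocorrelation structure of real climate
(variograms, anisotropy), coastlines/nodata geometry, sampling bias along
roads, taxonomic misidentification, and the empirical correlation structure
of the full 35-variable system. Passing tests therefore demonstrate that
the algorithms recover planted truth under controlled conditions — not that
real wild-tomato descriptor values are reproduced, which requires the
curated dataset and licensed rasters.

## Problem sizes and determinism

Default study size: 16 species × 200 accessions (+45 planted defects),
200×200 rasters, 19 continuous + 2 categorical layers; a full
simulate + run-all takes a few seconds on one CPU. Statistical checks use
n = 5,000 × 20 seeds for recovery and 500 replicates for test calibration.
All randomness flows from `numpy.random.default_rng` seeded from a single
integer; pipeline artifacts are byte-identical across reruns with the same
config and seed (the manifest contains no timestamps, and the config hash
is over the sorted config fields).

## Known limitations

- Complete-case handling discards a whole accession row for one missing
  layer; with ragged real nodata masks this can bias descriptor n.
- Bartlett's χ² is asymptotic; at small n with many variables the
  sequential tests are approximate (use the simulation calibration as a
  guide).
- The AEQD plane is exact in distance only from the anchor point;
  pairwise distances far from the centroid distort slowly (sub-1% at the
  ~1,500 km scale of the emulated study window).
- The screen's retained set depends on input column order only through
  documented tie-breaks; permuting columns can swap which of two exactly
  tied variables is kept (the log flags these).
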