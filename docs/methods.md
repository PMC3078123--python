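# Methods

## Grids and registration

All layers are regular geographic (WGS84) grids with square cells and
cell-center registration; the stored origin is the outer NW corner of the
first cell. Cell footprints are half-open — `[west, east) × [north,
south)` — so any in-extent point maps to exactly one cell, which makes
presence deduplication and station intersection deterministic. Longitudes
are normalised to [−180, 180); in-range values pass through unchanged so
no floating-point drift is introduced. Depth is positive-down metres
everywhere; bathymetry ingestion from elevation-convention sources negates
values and masks everything ≤ 0 as land. ESRI ASCII rasters are written
with 6 significant digits (bit-exact round-trips at that precision);
GeoTIFF (via `tifffile` with the ModelPixelScale/ModelTiepoint/GDAL_NODATA
tags) round-trips float64 exactly. Reprojection between CRSs is out of
scope.

## Up-scaling z-binned climatologies

A climatology arrives as one horizontal grid per standard depth level.
Depth levels are converted to contiguous half-open intervals `[top,
bottom)` with boundaries at midpoints between consecutive levels; the
first interval starts at 0 m and the last extends half the final spacing
below the deepest level (sources rarely publish bin edges; the midpoint
rule is the symmetric choice, and the original levels are stored so file
round-trips reproduce the identical binning). A cell depth on a boundary
belongs to the deeper bin's top — bins never overlap.

Each bin is (1) interpolated to an intermediate grid by inverse-distance
weighting — power 2, 12 nearest valid source cell centers, default 0.1°
resolution, distances in degree space — which closes the gaps that open
between adjacent bins on steep terrain; (2) resampled onto the bathymetry
by nearest-neighbour (containing-cell) lookup with no further
interpolation; (3) draped over the sea cells whose depth falls in the
bin's interval, and merged. IDW is exact at source cell centers and its
output always lies within the range of the neighbours used. Cells deeper
than the deepest bin keep the deepest bin's value: deep-water conditions
are comparatively stable, and the corals this package targets are not
found at those depths. Surface-only fields skip draping (interpolate,
resample, mask land). IDW runs on valid cell centers of the native grid
(not raw point observations).

## Terrain metrics

Slope uses Horn's 3×3 stencil on the depth surface with per-row
conversion of degree spacing to metres (spherical Earth, radius 6371 km),
output in radians, nodata where the neighbourhood is incomplete.
Windowed variants take a radius in kilometres, converted per row to whole
cells (minimum one); a cell's window uses its own row's east-west width.
Windowed slope smooths depth with the moving-average window first (planes
are preserved exactly). Rugosity is the ratio of triangulated 3-D surface
area to planar area within the window: the surface over cell centers is
split per quad along the NW–SE diagonal into two triangles at physical
(metre) coordinates; the ratio is exactly 1 on flat terrain and ≥ 1
always. BPI is mean window depth minus cell depth — positive on crests,
negative in depressions. Aspect is not implemented (not used by the final
model this package reproduces).

## Presences

Records are cleaned in three ordered steps, each logged: records outside
the stack extent are removed; records on cells where any layer is nodata
are removed (the model needs a complete covariate vector); within a cell
only the first record in input order is kept, so multiple observations in
one cell cannot weight the model toward that cell's conditions. The
combined multi-species set is the union re-deduplicated per cell.
Depth-implausible records are retained, not filtered: positional error is
handled downstream by the 10th-percentile threshold rationale.

## Maximum-entropy model

Features: linear, quadratic, pairwise-product and hinge transforms of the
covariates scaled to [0, 1], with the scaling extrema taken from the
presence + background pool and prediction inputs clamped to that range.
Feature classes switch on with presence count m (linear always; quadratic
m ≥ 10; hinge m ≥ 15; product m ≥ 80), mirroring the reference Maxent
auto-feature rule. Hinge features use 50 evenly spaced knots per variable
in each direction (forward and reverse). Threshold features are omitted —
hinge features supersede them in the reference implementation's default
behaviour as well.

Per-feature L1 penalties are `β_class(m) · max(std_j, 10⁻⁴) / √m` times
the regularisation multiplier (default 1), with `β_class` from the
published default tables: linear/quadratic/product interpolated on m
through (0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05); hinge constant 0.5.

The optimiser is proximal gradient descent (ISTA) with backtracking line
search on the regularised objective; backtracking guarantees the
regularised gain trace is non-decreasing, and the trace is stored on the
fitted model and asserted in tests. Iteration stops when the gain change
drops below the convergence threshold (default 10⁻⁵) or at the iteration
cap (default 500). Any convex optimiser satisfying those two properties
would be a conforming replacement. The Gibbs probabilities over the
background are normalised explicitly and sum to 1 to ~1e-16.

The logistic suitability uses the v3.2-era convention `HSI =
c·q/(1 + c·q)` with `c = exp(H)`, H the entropy of the fitted background
distribution; a zero-weight model is exactly uniform over the background
and maps to HSI 0.5 everywhere. Background: 10,000 cells drawn uniformly
without replacement from the cells valid in every layer, seeded; when the
region has fewer valid cells, all of them are used (with a warning) —
that is the normal situation for the desk-scale synthetic region.

## Evaluation

Presences are split 70/30 into training and test sets by a seeded uniform
permutation (train size = round(0.7·n)). AUC is the Mann–Whitney rank
formulation with midrank ties — the probability that a presence outranks
a random background cell — and is invariant under strictly monotone
transforms of the scores. Test gain is the mean `log(q(x)·N)` over test
presences (0 for the uniform model; densities below the double-precision
floor are clamped with a logged warning). The suitability threshold is
the 10th percentile of training-presence scores with linear interpolation
between order statistics (the reference implementation's convention is
undocumented; interpolation is deterministic and stated). Omission counts
scores *strictly below* the threshold, consistent with the ≥ rule of the
binary map, so on tie-free scores training omission never exceeds the
percentile. The reported test-AUC standard deviation comes from 10
re-partition replicates with derived seeds, refitting each time; the
replicate scheme is this package's choice. Significance against a random
prediction uses a two-sided Wilcoxon rank-sum test of the replicate AUCs
against matched null AUCs obtained by permuting presence/background
labels over the same score pool. Covariate screening reports the Pearson
correlation matrix over 10,000 seeded random valid cells and flags pairs
with |r| > 0.7 — flagged pairs are reported, not auto-dropped, because a
strongly correlated pair can still both be retained on the strength of
their individual contributions (as temperature and aragonite saturation
state are in practice); the retention decision is left to the analyst.
Whether omission should use test or training presences is genuinely
ambiguous in the field's reporting; both are computed, with the test-set
rate as the headline number.

## Layer validation

Bottle stations strictly deeper than 50 m are retained (near-surface
bottles do not describe seafloor conditions). Each station is paired with
the layer value of its containing cell — a horizontal match against the
seafloor layer; per-depth matching is deliberately not the default, since
the layer being validated *is* the seafloor representation. Agreement is
summarised by Pearson r and r², by mean profiles in half-open bins along
depth (50 m), latitude (5°) and longitude (10°) starting at the axis
minimum, and by a 5° grid of the mean difference, with the sign
convention layer − station (model minus observation).

## The synthetic world

The generator emulates the statistical structure the analysis assumes,
with planted truth for recovery tests. Defaults (the conditions all tests
and the acceptance script run under): a 60 × 80 cell region at 0.05°
(~4° × 3° of a mid-latitude margin), a land margin on the west, a 150 m
shelf ramping to a 4800 m abyssal plain, four Gaussian seamounts of
3000 m relief, 25 m depth noise. Three z-binned variables (temperature,
salinity, dissolved oxygen) live on a 4× coarser horizontal grid with ten
standard levels to 4000 m, so the deepest cells exercise the
deeper-than-deepest rule; each is a latitudinal linear surface gradient
decaying exponentially toward a uniform deep value, plus cell noise.
Temperature decays with a 2000 m e-folding scale (19 °C surface at the
reference latitude to 1 °C at depth): a full-depth profile with a gradual
deep decline keeps the driving covariate informative over the abyssal
plain — with a much shallower scale, deep temperature is effectively
constant and a temperature-driven niche is unidentifiable there for any
estimator, which would say nothing about the model.

The planted niche is a Gaussian-product response (default: temperature
optimum 8 °C, tolerance 1.5 °C — the restricted thermal envelopes
reported for framework-forming cold-water corals). Presences are sampled
without replacement with probability proportional to suitability
(Gumbel-top-k), which enforces one presence per cell by construction.
Bottle stations sit at the centers of random sea cells, take the cell's
seafloor depth, and read the z-bin slice covering that depth at their
position, plus optional Gaussian noise; with the IDW intermediate grid
matched to the field's own resolution (the generator's default),
interpolation is exact at the climatology grid points and noise-free
stations agree with the draped layer exactly (r² = 1). All generators are
bit-reproducible per seed; the pipeline derives per-stage sub-seeds from
one global seed.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: spatial sampling bias in
presence records, positional error, ocean circulation and water-mass
structure (fronts, upwelling), temporal variability, correlated
multi-variable niches, and the 60°N/marginal-sea coverage limits of real
carbonate-chemistry products. Recovery results here certify the
machinery, not real-world accuracy.

## Numerical choices and problem sizes

CSV outputs use a fixed `%.10g` float format so reruns are byte-identical.
Percentile and partition tie-breaks are stated above; IDW treats an
output point within 10⁻¹² degrees of a source center as coincident.
Degenerate inputs (no valid cells, empty score lists, < 3 validation
pairs, < 4 presences to partition, zero-variance layers) raise or flag
explicitly rather than returning silent NaNs. Tests and the acceptance
script run on the 60 × 80 default region (or smaller), with 100–300
presences and 5–10 evaluation replicates — sizes chosen so planted-truth
recovery is comfortably identifiable while the whole suite runs in a few
minutes on one core; the statistics of interest (AUC calibration,
threshold bounds, oracle equivalences) are size-independent.

## Known limitations

The IDW distance metric is degree-space Euclidean, adequate at the
mid-latitude desk scale but biased near the poles and the dateline;
grids must not cross the antimeridian. The optimiser is dense — feature
matrices of ~10⁵ background cells × ~10³ features fit easily in memory,
but a true 30-arc-second global run would need tiling and an out-of-core
design. Only annual-mean layers are supported (no monthly/seasonal
stacks), categorical covariates are not implemented, and the covariation
screen reports rather than resolves collinearity.
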