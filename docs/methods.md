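# Methods

## Model

`ecorange` implements a rectilinear environmental-envelope model with a
graded distance score.  The species' niche is represented by the
axis-aligned box of per-factor [min, max] ranges observed at its
occurrence points, plus the set of soil classes observed there.  The
assumptions are those of the envelope family:

* factors are treated independently — the envelope is a box, not a hull
  or a density, so factor interactions are captured only through the
  joint occurrence sample;
* presence records are informative about tolerances (the observed range
  is an inner estimate of the physiological range; it can only grow with
  more data, never overshoot);
* the categorical soil requirement is a hard filter: a cell is suitable
  only if its soil class was seen at least once at an occurrence.

Scoring proceeds in five steps per grid cell: (1) min–max normalization
of every continuous layer to a common 0–100 scale using the layer's own
valid-cell extremes; (2) per-factor range distance — zero inside the
normalized envelope interval, otherwise distance to the nearer bound;
(3) Euclidean aggregation across factors; (4) classification of the
distance surface with class 0 reserved for distance exactly 0; (5)
intersection of the class-0 cells with the soil mask.  The zero set of
the aggregate distance is exactly the envelope box, so the final mask has
a closed-form characterization that every synthetic test grid is checked
against cell by cell.

Normalization statistics deliberately come from the analysis stack, not
from the occurrence sample: the rescaling is a property of the layer.
Because the envelope bounds are pushed through the same affine map as the
cell values, the suitable set is invariant to the choice — normalization
matters only for how *distance* accumulates across factors with different
native units.  Nothing is clamped, so an envelope fitted on one stack
remains meaningful when transferred to another grid whose values exceed
the fitting stack's range (`Results.predict(new_stack)`).

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| envelope bounds | observed min/max | native | the fitted niche; `trim_percentile=p` optionally uses [p, 100−p] percentiles for outlier-heavy data (default off — full observed range first) |
| normalization targets | 0, 100 | — | common dimensionless scale; fixed |
| classification bins | class 0 = {0}; (0, Max_d] in 4 equal-width bins | normalized distance | presentation only — the final mask depends on class 0 alone |
| suitable classes | {0} | — | which distance classes count as suitable before the soil intersection |
| Earth radius | 6371.0088 | km | authalic radius for spherical cell areas |
| nodata sentinel | −3.4e38 | — | default when raster metadata is silent; far outside ecological ranges |

Tie and edge rules, fixed and documented: cell membership is half-open
(a point on a shared edge belongs to exactly one cell: east/below edges
exclusive, with the closed top realized by the floor of the row
coordinate); a distance exactly on a class threshold goes to the lower
(more suitable) class; quartiles in factor summaries use linear
interpolation between order statistics; occurrence rows invalid in *any*
factor (nodata or out-of-grid) are excluded from all factors' ranges
(complete-case), flagged with a reason rather than dropped.

## Synthetic landscape generator

The generator is first-class, tested code; it defines the conditions
under which the pipeline is validated.  Each continuous field is
`base + lat_slope·|lat| + trend + noise` with a three-component seeded
sinusoidal trend and i.i.d. Gaussian per-cell noise; soil is a
nearest-seed (Voronoi) mosaic over seeded random centres, with every
class guaranteed present; regions are a rectangular partition of the
extent (so area accounting can be checked for exact additivity); the
truth mask is computed *by definition* from the configured envelope, and
occurrences are drawn uniformly over its true cells, uniformly positioned
within the chosen cell.  All randomness flows from one
`numpy.random.SeedSequence`, so identical configs are bit-identical
across platforms.

The default configuration is a desk-scale analog of a global 1° analysis:
360 × 180 cells, the six continuous factors plus soil, and a true
envelope equal to the observed factor range of *Panax japonicus* (annual
mean temperature 2.6–22.3 °C, coldest quarter −7.0–14.3 °C, warmest
quarter 10.7–28.8 °C, precipitation 539–2273 mm, humidity 49.4–75.5 %,
radiation 118.7–157.6 W·m⁻²).  The field parameters (equatorial bases,
latitudinal gradients of −0.45…−0.85 °C/deg for the temperature factors,
trend amplitudes of a few native units, noise at roughly half the trend)
were chosen once as climatologically plausible values that make this
envelope a noisy mid-latitude band occupying a few percent of the globe —
large enough to sample, small enough that recovery is non-trivial.

What the generator does **not** emulate: the spatial autocorrelation
structure of real interpolated climate surfaces, cross-factor physical
coupling (e.g. temperature–humidity dependence), coastlines/ocean
masking, sampling bias in occurrence collections, and georeferencing
error.  Passing tests therefore demonstrate the *correctness of the
algorithm* (exact zero-set semantics, containment, monotonicity,
convergence of the fitted envelope with sample size), not the ecological
fidelity of any particular real-world prediction.

## Numerical choices

* Distance arithmetic is plain float64; the vectorized surface is
  required (and tested) to match a scalar cell-by-cell evaluation
  bit-for-bit up to 50 × 50 grids, so there is no hidden reassociation.
* Degenerate inputs fail loudly: constant layers cannot be normalized,
  empty envelopes and all-invalid samples raise, an envelope that
  excludes the whole synthetic landscape rejects the config.
* A `Min_d > 0` surface (no perfectly suitable cell) degrades gracefully:
  class 0 is simply empty and the final mask all-false.
* Cell areas use the exact spherical-zone formula
  `R²·Δλ·(sin φ_top − sin φ_bottom)`; the full 1° global grid reproduces
  4πR² to 1e-6 relative, and per-region partition sums are exact to
  1e-9 relative.
* Region assignment is by cell centre, first containing region wins (set
  order); cells in no region are reported under `(unassigned)` so the
  area-conservation invariant stays checkable.

## Design choices

* **Model/Results API.**  The top-level interface follows the
  statistical-modelling convention: a model object built from data,
  `fit()` returning a results object with the estimates, diagnostics and
  a `summary()` table.  The stage functions remain importable for
  pipeline use; the CLI (`simulate / extract / envelope / score /
  summarize / run`) is a thin layer over them.
* **GeoTIFF I/O on tifffile.**  Rasters are written with explicit
  GeoTIFF tags (pixel scale, tiepoint, geokeys, nodata) rather than
  through a GDAL binding; readers refuse projected rasters instead of
  silently reprojecting.  ESRI ASCII grids (including centre-registered
  headers, converted on ingest) are supported for interchange.
* **No buffer around the envelope.**  A cell is suitable only at
  distance exactly 0; a tolerance band would trade the exact zero-set
  characterization for a tunable knob.
* **Single-cluster envelopes.**  Each species is one envelope;
  multi-modal niches (disjoint clusters) are out of scope.

## Problem sizes

The test suite fits on small landscapes (30 × 40 two-factor grids) for
unit and property checks, 20 × 20 – 50 × 50 grids for the bit-for-bit
oracle comparisons, and the full 360 × 180 default landscape with n = 500
and n = 5000 occurrences for envelope-recovery checks; the whole suite
runs in well under a minute.

## Limitations

* The envelope is an inner estimate: with few points it under-covers the
  true range (visible in the n = 500 vs n = 5000 Jaccard gap), and it is
  sensitive to coordinate errors that land points in extreme cells (the
  percentile-trim option mitigates, at the cost of guaranteed training
  containment).
* Equal-angle grids over-represent high latitudes in the *count* of
  cells; areas are correct, but envelope fitting weights each occurrence
  point, not each km².
* No reprojection, no partial-cell (areal-weighted) zonal statistics, no
  probabilistic output, and no variable-importance analysis — the score
  is a geometric distance, not a likelihood.
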