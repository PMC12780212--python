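# Methods

This note documents the models implemented in `hfmap`, the defaults and
why they are what they are, the numerical choices, and what the synthetic
test bed does and does not demonstrate.

## Grid and data model

All layers live on a shared projected grid with meter units, square pixels
(default 30 m), a top-left origin and row-major storage; pixel centers are
at `origin + (index + 0.5) · pixel_size` and every distance is
center-to-center. Operations never reproject: layers must already share a
CRS identifier, and reprojection is treated as an input-preparation
contract outside the package (`regrid` only resamples within one CRS).
Nodata sentinels default to −9999 for continuous and 255 for categorical
layers.

Rasterization burns polygons by pixel-center containment and lines/points
on every touched pixel (an Amanatides–Woo grid traversal per segment);
overlaps resolve by maximum, matching the downstream combination rule, so
burn order never matters. Resampling is bilinear for continuous layers and
modal (over contributing source-pixel centers, nearest-neighbour when
upsampling) for categorical ones; a categorical resample can therefore
never invent a category code.

## Pressure scoring

The scoring template fixes criterion importances (4, 3, 2, 1) for cover
loss, imperviousness, habitat viability and pollution risk; a dataset's
maximum score is the importance-weighted sum of its qualifications and is
the hard cap applied after every scoring case.

Numerical decisions worth recording:

* **Logarithm base.** The population rules use base-10 logarithms. With
  natural logarithms the count coefficient 5.41 would give ≈ 23 at
  70 persons/pixel; base 10 gives 10.016, consistent with the saturation
  of the score at 10 near that threshold.
* **Decay functional form.** Distance decay is specified only as
  "exponential" with an origin score and a maximum distance, so the rate
  is calibrated to pass through a configurable floor (default 0.1) exactly
  at the maximum distance: `s(d) = S0 · exp(−d · ln(S0/floor) / D)`, hard
  zero beyond D. This preserves both stated anchors; the floor is the one
  free parameter and is exposed everywhere decay is used.
* **Point features.** "Actual location" points burn their score on every
  pixel whose center lies within the footprint radius (wells 50 m,
  filling stations 150 m, refineries/deposits 500 m, electrical points and
  mines 50 m); "approximate location" points (settlements, ports, score
  7.5) burn the point pixel and receive a halo decaying from 4 to zero at
  100 m. Where halo and direct scores overlap the pixelwise maximum in the
  pressure combination resolves it.
* Scores are stored as float64; every scored raster is clipped to the
  dataset maximum after its case runs.

The default category scores (urban 10, runways 8.75, sparse houses and
settlements 7.5, Peru pasture 5.5 / agriculture 5.25, unified Ecuador LULC
5.25, tree plantations 4.5, primary roads/railways 8.75, secondary roads
8.25, country roads 6, trails 1.25, pipelines 5.25, transmission lines 5,
electrical point infrastructure 9 or 8.25, oil and gas points 10, mining
7.25) ship as configuration defaults and are all derivable from the
template rows.

## Accessibility (indirect pressure)

The friction surface follows a fixed precedence — roads > coastline >
waterways > agricultural walking > natural-vegetation walking — taking the
first applicable rule per pixel. Decisions:

* **Sources.** Built-environment pixels are read as zero-traversal-cost
  sources seeding the shortest-path queue at time 0 (a literal "0 km/h"
  would make habitation impassable, which is not the intent). Only
  8-connected clusters of at least two pixels count as habitation;
  isolated single pixels are treated as data artifacts.
* **Moves and costs.** Movement is 4-connected ("horizontally or
  vertically"); a step costs the arithmetic mean of the two pixels'
  crossing times — the standard accumulated-cost convention, implemented
  with `skimage.graph.MCP_Geometric` and cross-checked in the tests
  against an independent Dijkstra oracle.
* **Slope clamping.** Both walking formulas diverge as slope → 0 (the
  power law grows without bound; the log formula tends to +∞ the other
  way), so slope is clamped to ≥ 1% before evaluation, and natural-walking
  speed is floored at 0.1 km/h (the log formula goes negative near 1000%
  slope). Both constants are `SpeedModel` fields.
* **Water.** Navigable waterways and the coastline enter as rasterized
  lines carrying the matrix/coastal speeds; water pixels off any navigable
  line are barriers (infinite crossing cost).
* **Horizon and scoring.** Travel time is scored with the same calibrated
  decay, from 4 at the source to the floor at the 4-hour routine-travel
  horizon and zero beyond. Unreachable pixels score 0, not nodata:
  unreachability is an absence of routine influence, not missing data.
* **Tiling.** For extents that exceed memory the grid is tiled with
  overlaps and mosaicked by pixelwise minimum. The tiled surface can never
  underestimate the untiled one, and equals it wherever a shortest path
  stays inside a single (overlap-expanded) tile; tests verify exact
  equality under full overlap.

## Assembly

Datasets of one pressure combine by pixelwise maximum (nodata ignored
unless universal). The HF index is the pixelwise **sum** of the eight
pressure layers — the aggregation in the global-HF lineage — with the
indirect pressure entering as its own summand. Water is masked to nodata
and values rounded half-even to two decimals, once, at the end. An
optional linear display rescale onto 0–30 exists for presentation
parity but is off by default and never feeds analysis. Classification
uses left-closed intervals [0, 1), [1, 4), [4, 15), [15, ∞).

## Validation protocol

The reference map is reclassified into four strata with breaks 4 / 8 / 18;
the printed bound of the top stratum is read as "≥ 18" (the alternative
reading would overlap the medium stratum). Compromise allocation starts
proportional to stratum area (largest-remainder rounding) and raises each
stratum to a floor, taking the excess from the currently largest stratum;
counts always sum to the requested total, which is a configuration input
(derived sample-size formulas are not re-implemented). Plot draws are
uniform without replacement within each stratum, with plot centers on
pixel centers, 300 m plots and 5 km buffers.

Visual scores standardize as `(score / 3) · pressure maximum`, except the
indirect pressure whose presence maps to the fixed stand-in value 2;
components combine by maximum within a pressure, pressures sum, and the
total is divided by the sum of the pressure maxima so both the visual
index and the extracted HF live on [0, 1] before any metric. The
tolerance kappa counts a pair as agreeing when the two indices differ by
strictly less than the tolerance (default 0.20); chance agreement is the
agreement rate over all ordered cross pairs, which avoids imposing an
arbitrary binning on continuous scores and is computed in chunks so large
samples stay cheap. RMSE is the root mean squared paired difference and
R² the squared Pearson correlation; zero-variance inputs flag R² as
undefined (NaN with a warning) rather than inventing a value.

## Synthetic landscapes

The generator emulates the statistical shape of the national input stack
on a desk-scale grid (default 500 × 500 pixels at 30 m): smooth terrain
from filtered Gaussian noise (elevation 50–3500 m, slope by finite
differences in percent rise), patchy categorical land cover assigned by
rank quantiles of a second smooth field (fractions hit exactly by
construction; defaults: forest 0.53, flooded forest 0.05, shrub 0.10,
agriculture 0.12, pasture 0.08, plantation 0.03, water 0.04, urban 0.05 —
a forest-dominated tropical mix with a visible agricultural frontier),
settlements at urban-patch cores, a road network from the settlement
minimum spanning tree classed by corridor length, rivers along terrain
minima, a western coastline, clustered point infrastructure, log-normal
urban population (log-mean 3.2, so city pixels exceed the 70-count
saturation), and radiance as blurred population plus gas-flare hotspots
above the 60-unit linear-scoring threshold. Everything is deterministic
per seed.

Two synthetic "visual interpreters" exist. The **imagery** mode scores
plots from the landscape truth through the 0–3 coverage/occurrence bands,
as a human would, with band-flip noise. The **pipeline** mode reads the
pipeline's own pressure layers at each plot, rounds the sum to the map's
two-decimal precision and normalizes — exactly inverting the
standardization, so with zero noise the protocol recovers the map
perfectly (kappa = 1, RMSE = 0, R² = 1). The pipeline mode is the
end-to-end correctness check: quantization-free recovery isolates the
protocol's arithmetic. What these tests demonstrate is internal
consistency of scoring, aggregation, sampling and metrics; they say
nothing about how well a real visually interpreted index tracks a real
landscape, where imagery quality, interpreter judgment and the 0–3
banding all add error.

## Problem sizes

Defaults were chosen so a full run is interactive on a laptop: the
standard landscape is 500 × 500 pixels (15 km × 15 km), the travel-time
oracle comparisons run on 20 × 20 grids, tiling equivalence on 200 × 200,
and validation samples 120 plots with a floor of 10 per stratum.

## Known limitations

* No CRS reprojection; inputs must be pre-projected onto one grid.
* The accessibility model inherits the stated simplifications of its
  family: no directional slope effects, seasonality, mode-transfer times
  or port/station effects, and it is sensitive to the speed model.
* The exact aggregation formula ("sum") and the 0–30 presentation scale
  are modelling choices of this package; the display rescale is isolated
  and off by default.
* The decay floor (0.1) and the sub-1% slope behaviour are explicit,
  configurable substitutes where the source material is silent.
* Synthetic landscapes are statistical stand-ins, not geography; mining
  is not differentiated by type or scale, and qualifications are inputs,
  never derived from data.
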