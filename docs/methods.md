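# Methods

## Problem and model

The package estimates physical access to healthcare: for every cell of a
planar raster, the minimum travel time to the nearest healthcare facility,
and from that, population-weighted statistics describing how far adults aged
60 years and older live from care. Two facility classes are analyzed
side by side — hospitals only, and facilities of any type — because access to
hospital-based care and access to any point of care answer different policy
questions.

The landscape is modelled as a cost (friction) surface at 100 m resolution.
Each cell carries one traversal speed:

| class                      | speed    | mode    |
|----------------------------|----------|---------|
| motorway / primary road    | 100 km/h | vehicle |
| secondary road             | 50 km/h  | vehicle |
| tertiary road              | 30 km/h  | vehicle |
| barren land, built-up area | 5 km/h   | walking |
| forest                     | 2 km/h   | walking |
| open water / rivers        | barrier  | —       |

Roads override land cover in the same cell, including water: a road crossing
water is treated as a bridge. This merge order is the standard convention of
raster accessibility tools; the alternative (water beats roads) would sever
every river crossing and is not offered. Rivers are water cells in the
land-cover raster; there is no separate vector burn-in. Travel speeds do not
vary by time of day, and the model is isotropic: an optional Tobler-style
exponential slope correction of walking speed from the elevation layer exists
but is **off by default** and is an extension of, not part of, the core
model.

## Cost distance

Cells are nodes of an 8-connected graph restricted to non-barrier cells. The
edge between adjacent cells *a*, *b* costs

    t(a,b) = d(a,b) · ½(1/v_a + 1/v_b)

with *d* the center-to-center distance (cell size for axis moves, cell
size·√2 for diagonal moves). The half-pace convention charges each cell at
its own speed for half the crossing — the natural discretization of a
piecewise-constant speed field — and is frozen; destination-cell-cost
conventions give systematically different times near speed transitions and
are deliberately not configurable.

Travel time is the exact multi-source Dijkstra distance (no hierarchical or
approximate routing) from the set of facility cells. The priority queue
orders entries by (time, row, col), so expansion order and output are
bit-stable across runs and platforms. Facilities are snapped to their
containing cell; a facility on a barrier cell snaps to the nearest
traversable cell within 10 cells (Euclidean cell distance, ties broken by
(row, col)) or is dropped with a warning. Unreachable cells keep the +inf
sentinel through every later stage (on disk: −1, documented in the file
header convention); they are never replaced by a large finite time.

Administrative regions never clip the graph: travel may cross region borders
at no cost, and regional summaries are computed afterwards by attributing
1 km cells to regions by cell-center point-in-polygon.

The 100 m travel times are aggregated onto the 1 km population grid as the
mean of the finite sub-cell values per 10×10 block (configurable to min or
median; mean is the default because a 1 km cell's population is spread over
the block, not concentrated at its fastest corner). A block whose traversable
cells are all unreachable stays unreachable; an all-barrier block becomes
nodata.

## Statistics

All summaries weight 1 km cells by their 60+ population count.

* **Category shares** use closed-left bins: hospital scheme <2 h, 2–6 h,
  6–12 h, >12 h (boundaries 120/360/720 min); any-facility scheme <1 h,
  1–2 h, 2–6 h, >6 h (60/120/360 min). A cell at exactly 120 min falls in
  2–6 h. Unreachable cells sit in the open-ended top category and above every
  cut-off.
* **Proportion beyond a cut-off** comes with a Wilson score 95% CI
  (z = 1.959964). The binomial denominator *n* is an explicit, mandatory
  choice: raster population counts are not independent Bernoulli draws, so
  the caller passes an effective sample size or selects the number of
  populated 1 km cells. Published CIs from comparable national analyses are
  not reproduction targets here, since their effective *n* is generally
  unstated.
* **Worst quintile**: cells sorted by travel time; the top 20% of population
  mass is taken, splitting the boundary cell's weight exactly; its weighted
  median and quartiles use linear interpolation on mid-cumulative weights
  (Hazen convention: position (cum − w/2)/W). With unit weights on 1..100
  this puts the top-fifth median at 90.5, matching direct enumeration. By
  default unreachable cells enter as +inf, so a quintile median landing on
  them reports "unreachable"; a flag drops them instead.
* **Populated-area maps** mask cells with fewer than one adult 60+ per km².
* **Facility densities** are 100 000 · count / population, reported to three
  decimals. Pooling of the OSM and MFL registries is a plain union without
  deduplication — nearest-facility time is invariant to co-located
  duplicates — with a cross-source proximity count available as a diagnostic
  that never alters the analysis set.

## Synthetic landscapes

The generator produces the spatial structure the statistics are sensitive to,
not realistic geography: contiguous water and forest blobs (thresholded
Gaussian-smoothed noise), settlements with built-up halos, a road network
joining settlements (Euclidean minimum spanning tree; longer trunk edges get
faster classes), a 60+ population clustered at settlements by isotropic
Gaussian kernels with unequal settlement weights (zeroed on majority-water
1 km cells, normalized to the requested total), and two facility registries
placed near settlements on non-water cells, with a configurable fraction of
OSM points duplicating jittered MFL locations to emulate un-deduplicated
registry overlap.

Defaults (8 settlements, 3 km settlement spread, 8% water, 25% forest, 30%
registry overlap, hospitals a small minority of facilities) describe a
plausible mixed rural landscape; the clustering knobs are free parameters of
the synthetic world, not calibrated to any real surface. What passing tests
on these worlds demonstrate is the correctness of the *computation* —
shortest paths, aggregation, weighting, intervals — not the realism of any
particular country's access estimates: real population surfaces have
dasymetric small-scale structure, real road networks have cycles and
class-mixing, and real registries have geocoding error, none of which the
generator emulates.

All generators are pure functions of (scenario, grid); the scenario's single
integer seed is split into named, independent substreams per stage, so
regenerating any layer is bit-identical.

## Numerical choices and degenerate inputs

* Dijkstra is exact; oracle tests require ≤1e-9 relative agreement with an
  independently built explicit-edge-list shortest path.
* Speeds are validated positive; a barrier is the absence of a speed, not a
  zero speed. An all-barrier friction surface is legal and yields an
  all-unreachable travel-time raster; snapping then fails with a clear error
  because no source is traversable.
* Fine and coarse grids must nest exactly (integer cell-size ratio, exact
  dimension multiples); anything else is an error, never resampled silently.
* Zero total population makes proportions and quantiles undefined and raises;
  an empty histogram region returns a zero-mass table.
* The Wilson interval is clamped to [0, 1] and to contain p̂ (guards the
  last-ulp rounding at p̂ ∈ {0, 1}).
* Summary CSVs are written with a fixed float format, making repeat runs
  byte-identical.

## Problem sizes

The test suite runs synthetic worlds between 50×50 and 500×500 model cells
(0.25–2 500 km²-equivalent at 100 m). The oracle-equivalence suite covers 100
random friction grids up to 50×50 with random barriers and 1–5 sources; the
monotonicity suite covers 50 random scenarios at 50×50. The acceptance script
runs a 300×300 model grid (30×30 population cells). These sizes were chosen
so the full distribution-level behavior (multiple settlements, barriers,
unreachable pockets) appears while any single run stays in seconds; the
algorithms are O(E log V) in the cell count and have been run at 500×500
within the suite.

## Known limitations

* Vector-network routing, transport schedules/frequencies, and anisotropic
  (slope-signed) costs are out of scope; travel time is a raster
  approximation with assigned, not measured, speeds.
* The 8-connected √2 metric overestimates some Euclidean shortest paths by up
  to ~8% (the chamfer bound); this is inherent to raster cost distance.
* Facility registries are taken at face value: no deduplication, no
  readiness/quality data, no referral structure.
* The Wilson CI quantifies binomial sampling noise for a user-chosen *n*
  only; it does not propagate facility-location or population-surface error.
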