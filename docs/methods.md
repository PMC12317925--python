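# Methods

## Model

An agent occupies one cell of a lattice overlaid on a cost raster and, at
each timestep, moves to the minimum-mean-cost cell of its single-ring
neighbourhood (its decision catchment). The model deliberately assumes no
prior knowledge of the terrain: it is a greedy, locally informed walker,
not a global least-cost-path solver. Randomness enters in exactly three
places — the optional random start cell, tie-breaking among equal-cost
candidates, and the fallback draw when every candidate has already been
visited — so on terrain with unique local minima the walk is fully
deterministic given its start.

### Lattice geometry

* **Square**: cells indexed `(i, j)` with row 0 at the north edge; cell
  centre `anchor + ((j+0.5)·nsize, −(i+0.5)·nsize)`. The Moore ring has 8
  members; orthogonal neighbour centres are `nsize` apart and diagonal
  ones `nsize·√2`.
* **Hex**: pointy-top axial coordinates `(q, r)`; centre
  `x = anchor_x + nsize·(q + r/2)`, `y = anchor_y − nsize·(√3/2)·r`. The
  cell "size" parameter is defined as the centre-to-centre spacing of
  adjacent hexes, which makes all six step lengths exactly `nsize`; the
  hexagon footprint (the Voronoi cell of the centre lattice) therefore has
  circumradius `nsize/√3`. Note that a pointy-top hex lattice has no
  direct north/south step: vertical travel alternates NE/NW (or SE/SW)
  moves.

The lattice anchor coincides with the raster origin, and a walk starts in
the lattice cell containing its start coordinate. This gives a single,
documentable mapping between world coordinates, lattice cells and raster
pixels.

### Cost aggregation

A neighbourhood cell's cost is the arithmetic mean of the raster values
whose **pixel centres** lie inside the cell footprint, NoData excluded.
Centre membership (rather than area weighting) was chosen because it
generalises cleanly to hexagons and to `nsize` values that are not integer
multiples of the resolution. Membership on shared boundaries uses a fixed
half-open rule — left/top edges inclusive — implemented by nudging test
points by `1e-9·resolution` east and south before the point-in-polygon
test; this makes the lattice an exact partition of the plane, so a 200 m
square cell over a 100 m raster always aggregates exactly 4 values. When a
footprint is smaller than a pixel and contains no centre at all, the cost
falls back to the raster value at the footprint centroid, keeping
sub-resolution catchments well defined. A cell whose valid-value set is
empty (all NoData, or outside the raster) is invalid and drops out of the
candidate ring exactly like an out-of-extent cell.

### Transition rule, ties, revisits, edges

Candidates are the ring cells whose footprints lie **fully** inside the
raster extent and have a valid cost. Among unvisited candidates the
minimum-cost cell is chosen; ties are declared within relative tolerance
1e-9 (with a 1e-12 absolute floor so exact-zero costs on flat terrain can
tie) and resolved by a uniform draw — exact float comparison would make
the ties that flat or integer-valued terrain produces vanish. "Visited"
means lattice cells the agent has occupied, not raster pixels merely
crossed. When all candidates are visited, the next cell is drawn uniformly
from the full candidate set and the event is logged on the walk
(`fallback_steps`), which is what makes the no-see-saw property auditable.
A walk terminates early, with status `hit_edge`, only when the candidate
set is empty; walks may hug the map edge indefinitely, which is the
permissive reading of edge behaviour and matches the foothill-hugging
walks the model is meant to produce.

Candidate enumeration order (clockwise from north for squares, from east
for hexes) is fixed and documented because the tie-break draws an index
into it: seeded runs are bit-reproducible across platforms only under a
fixed order.

### Batches and reproducibility

Walk `k` of a batch draws from `numpy.random.default_rng([master_seed, k])`
— an independent, scheduling-invariant substream per walk — so a batch is
reproducible bit-for-bit whatever the execution order. Random starts use
rejection sampling: uniform points in the raster extent are mapped to
their containing lattice cell until a fully interior, valid cell is found;
interior cells have equal area, so the accepted cell is exactly uniform
over valid interior cells.

### Walk-density raster

The density layer counts, per raster pixel, the number of *distinct* walks
that crossed it (not the number of visits): each walk's polyline of
consecutive cell centres is rasterised with a supercover grid-traversal
algorithm — every pixel the segment passes through is marked, and exact
corner crossings mark both adjacent side pixels — and each walk increments
a pixel at most once. Rasterising the line segments (rather than marking
only occupied lattice cells) keeps traces connected when `nsize` spans
many pixels.

## Walk statistics

Per walk: total distance (sum of step lengths), resultant distance
(straight-line start→end), walk deviation `100·(total−resultant)/total` %
(defined as 0 % for a zero-length walk, and 100 % for a closed loop), and
the azimuth of the resultant by the quadrant method: base angle
`arctan(|ΔE|/|ΔN|)` with corrections NE `θ`, SE `180−θ`, SW `180+θ`, NW
`360−θ`, measured clockwise from **grid** north (no convergence-angle
correction). A zero-displacement walk has no azimuth; such walks are
excluded from (not zero-filled into) circular tests and rose bins.

Circular uniformity of a sample of azimuths is tested two ways:

* **Rayleigh**: `Z = n·R̄²` with mean resultant length `R̄`; p-value by the
  standard small-sample series
  `exp(−Z)·[1 + (2Z−Z²)/(4n) − (24Z−132Z²+76Z³−9Z⁴)/(288n²)]`, clipped to
  [0, 1]. Powerful against unimodal alternatives only.
* **Kuiper (modified)**: raw `V = D⁺ + D⁻` of `θ/360` against the uniform
  CDF; the reported statistic is the Stephens-stabilised
  `V* = V·(√n + 0.155 + 0.24/√n)`, whose critical points are essentially
  sample-size-free, and the p-value is the asymptotic series
  `Σ_k 2(4k²V*²−1)·exp(−2k²V*²)` truncated below 1e-10. The statistic is
  invariant under rotation and reflection of the sample, making the test
  origin-free on the circle and sensitive to multimodal departures. The
  modified form is the one consistent with a statistic of 1.834 at n = 100
  falling between the 5 % and 2.5 % significance points, and `n ≥ 5` is
  required because the asymptotic p-value is unreliable below that.

Rose-diagram bins are half-open sectors `[k·w, (k+1)·w)` (360° wraps to
bin 0) with `sqrt(count)` heights, so petal area is proportional to count
and `Σ height²` recovers the sample size. The bin width is a free
parameter (CLI default 15°); no particular width is claimed as canonical.

## Surfaces

GeoTIFF rasters are read and written through tifffile with the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA, and a
minimal GeoKey directory for an EPSG code); ESRI ASCII grids are supported
as a plain-text alternative. Non-square pixels and unselected multi-band
files are rejected. Slope can be derived from a DEM with Horn's 3×3
weighted finite differences (`slope = arctan√(p²+q²)`, in degrees), the
de-facto GIS standard; border cells and any cell with NoData in its 3×3
window are NoData, and slope is invariant to constant elevation offsets.

The synthetic generator produces the terrain structures the walker is
designed around, so every stage is testable without external data:

* `tilted_plane` — linear cost ramp; greedy descent is unique and exactly
  predictable (oracle fixtures). Note that a plane tilted along one axis
  only makes the three down-gradient Moore neighbours tie.
* `parabolic_valley` — a low-cost trough with quadratic walls, the
  analogue of a river corridor: walks starting on the walls descend to and
  then follow the trough.
* `random_field` — Gaussian white noise smoothed to a stated correlation
  length, normalised to mean 10 and standard deviation 3 (clipped at 0) —
  typical of a slope map, in degrees, of rolling terrain. Default
  correlation length is 10 pixels.

What the synthetic surfaces do **not** emulate: anisotropy (uphill vs
downhill cost), real drainage-network topology, DEM error, and
multi-variable composite suitability. Tests passing on these fixtures
demonstrate the mechanics of the model and statistics, not ecological or
archaeological validity on real terrain.

## Exports

Walks are exported to GeoPackage (written directly as an SQLite container
per the OGC GeoPackage 1.3 layout with standard binary geometry headers):
a `points` layer (one feature per visited cell centre, with run id and
step index) and a `lines` layer (one polyline per walk, with run id,
status, total and resultant distance, deviation % and azimuth). Density
goes to GeoTIFF aligned bit-exactly to the input grid; per-walk statistics
and rose bins to CSV; and the full configuration (including the master
seed and software version) to a JSON manifest, which together with the
inputs fully determines every output.

## Numerical choices and limitations

* Tie tolerance 1e-9 relative (1e-12 absolute floor); membership nudge
  1e-9·resolution; hex step-length equality holds to ~1e-15 relative
  (floating error of centre arithmetic).
* The density layer's supercover traversal breaks ties at exact corner
  crossings conservatively (both side cells marked).
* Problem sizes in the test suite and acceptance script — e.g. batches of
  100 walks × 1000 steps on 256×256 surfaces, 1,000-sample calibration of
  the circular tests at n = 100, 50-seed oracle sweeps on 20×20 grids —
  were chosen as the package's reference configurations; larger runs scale
  linearly in steps × runs.
* The walker is memoryless beyond its visited set: no prior-knowledge
  weighting, no anisotropic or metabolic cost, no goal seeking, no
  interacting agents, single-ring catchments only.
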