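# Methods

## Model

The landscape is a node-based resistor grid: every non-NoData raster cell
is a graph node carrying the cell's movement cost; edges join neighboring
valid cells. Edge conductance combines the two incident cell costs:

* `averaging="conductance"` (default): g = (1/c_a + 1/c_b) / 2
* `averaging="resistance"`: g = 1 / ((c_a + c_b) / 2)

Connectivity is 8-neighbor by default (4-neighbor available); with
`diagonal_scaling=True` diagonal edges have their resistance multiplied by
√2 to reflect the longer traverse. The defaults mirror the most common
configuration of raster circuit tools; all three choices are explicit
constructor arguments because published analyses vary in them and results
are not comparable across configurations.

For a node pair (s, t), the solver computes node potentials v with
L v = e_s − e_t (unit current, t grounded), giving the effective
resistance R_eff = v_s − v_t, edge currents I_e = g_e Δv, and per-cell
current c_i = ½(Σ|I_e incident| + |injection_i|) — throughflow at interior
cells, exactly 1 A at the two terminals. The per-cell current convention is
a definition, not a derived quantity; it makes the cumulative map's
terminal cells comparable across pairs.

### Linear algebra

Per connected component, one node is grounded and the reduced Laplacian is
factorized once (sparse LU up to 150,000 unknowns; above that a
Jacobi-preconditioned conjugate gradient with relative tolerance 1e-10).
Each node's reduced-inverse column is solved once and cached; any pair's
potential field is the difference of two cached columns re-referenced to
the pair's own ground. This is algebraically identical to grounding one
terminal per solve, and turns an n-node pairwise analysis (n(n−1)/2
solves) into n linear solves plus cheap vector arithmetic. Node pairs in
different components are recorded as unreachable (`inf`) and excluded from
indicators with a logged count, never silently averaged.

The verification oracle computes resistance distances densely per
component as R_ij = L⁺_ii + L⁺_jj − 2 L⁺_ij with the pseudoinverse formed
by exact rank-one deflation of the known nullspace, L⁺ = (L + J/m)⁻¹ − J/m
(J the all-ones matrix over the component). A generic SVD pseudoinverse is
unreliable here: on ill-conditioned cost mosaics the numerically-zero
singular value can survive the default cutoff and corrupt the result by
orders of magnitude.

## Indicators

* **MPER** — mean of R_eff over unordered reachable pairs; SE is the
  sample standard deviation of the pairwise values over √n_pairs. Pairs
  sharing a node are not independent, so the SE is descriptive, not an
  inferential standard error; this is stated in the report metadata. A
  per-node SE variant would also be computable; the pair-based definition
  is the package default.
* **ΔMPER** — difference in MPER against a baseline fitted on the *same*
  node set (enforced; comparing different sentinel sets raises). Positive
  means connectivity loss. Because lowering any cell cost can only lower
  every effective resistance (Rayleigh monotonicity) and raising can only
  raise them, development edits give ΔMPER ≥ 0 and park edits ΔMPER ≤ 0
  deterministically — the test suite asserts this over replicate random
  scenarios, and a new park lowers MPER even when it is not a node.
* **Node isolation** — mean R_eff from one node to the others; the grand
  mean of isolations equals MPER exactly (to 1e-12 in tests) when no pair
  is unreachable.
* **Current-map agreement** — Spearman rank correlation at 1,000 (default)
  distinct valid pixels sampled without replacement under a seed;
  average-rank ties.

## Cost surface and edits

The five-rank scheme (0.1 / 1 / 10 / 100 / 1000) is taken as given.
The protection overlay lowers cells *exactly at* the natural rank (1)
inside park footprints to the protected rank (0.1); higher-cost cover
inside parks keeps its cost. Exact comparison is safe because costs come
from the discrete scheme. The overlay is idempotent and only ever lowers
values; development edits only ever raise them — both are property-tested.

Rasterization uses the cell-center rule (a cell belongs to a footprint iff
its center is inside); parks covering no center collapse to their centroid
cell. Road lines are traced all-touched by dense sampling at a fifth of
the cell size, with a bridge cell inserted wherever the trace steps
diagonally, so a 1-cell-wide barrier cannot leak under 4-neighbor
connectivity. Scenario chains are built by sequential application on
copies; each step's ΔMPER is taken against its predecessor, with
development and park chains accounted separately.

## Sentinel selection

Candidates are filtered by designation class, minimum area (one raster
cell; the boundary case is retained) and an optional island flag — there
is no attempt to infer insularity from hydrography. Selection then draws
parks uniformly at random per zone (without replacement, seeded), accepting
a draw iff its centroid is at least the minimum proximity (default 100 km,
planar distance in projected map units) from every previously accepted
centroid across all zones; the attempt budget is 10,000 per zone. Quota
shortfall is a first-class outcome reported in the result (real landscapes
can make quotas infeasible); `SentinelSet.add_manual` lets an analyst top
up, re-verifying spacing themselves. Node placement: the centroid cell if
it carries the park's lowest cost class, else the nearest in-park cell with
that class (Euclidean between cell centers, ties row-major).

## Node-count sufficiency

The sweep computes the full-complement cumulative map once, then for each
k draws an *independent* random k-subset (subsets are not nested), records
the Spearman correlation of its map against the full map, its mean current
and its MPER. The sufficiency rule is explicit since an asymptote is
otherwise judged by eye: the smallest k from which rho stays at or above
the threshold (default 0.99) for every larger k in the table.

## Synthetic data

The generator emulates a patchy, mostly-natural cost mosaic: Gaussian-
filtered white noise (sigma = autocorrelation length, default 5 cells)
thresholded at its own quantiles so class fractions hit their targets
(defaults: 20 % cost 10, 10 % cost 100, 5 % cost 1000, remainder natural),
plus straight barrier-cost polylines (default one per 100 columns)
standing in for highways and rivers. Parks are buffered random points
(default 60 points, 300-m buffers on a 300-m grid — footprints of 1–9
cells), so park size and shape do not confound node-count experiments.
Scenario footprints are compact rectangles of ceil(area/cell_area) cells
placed where the neighborhood mean cost falls in the requested tercile of
the landscape's own distribution (the context labels have no absolute
definition); developments get a straight road polyline to the nearest
existing barrier cell.

What the generator does *not* emulate: real geography (lakes, coastlines,
the strong north–south land-use gradient of real study areas), realistic
road-network topology, or NoData structure from map projection. Passing
tests on synthetic mosaics therefore demonstrate the *mathematical*
contracts (oracle agreement, monotone indicator response, selection and
sweep structure), not that any particular real landscape's indicator value
would be reproduced.

## Problem sizes

Default experiment sizes are chosen so the full suite runs comfortably on
a single CPU: oracle comparisons on 50 random grids up to 30×30;
directional-response checks over 20 replicate 45×45 landscapes; the
node-count sweep on one 100×100 landscape with 60 parks (59 maps), with
10 replicate sweeps on the coarser k-grid {5, 10, 15, 20, 30, 40, 50, 60}
for the monotonicity check; the selection contract over 100 seeded runs on
150 synthetic parks. Each replicate sweep shares the cached node columns,
so cost grows with the number of distinct pairs, not raw solves.

## Known limitations

* Pairwise mode only; all-to-one and omnidirectional modes are out of
  scope.
* MPER is not bounded by the cost-rank range in general: long series paths
  accumulate resistance, so no such bound is asserted even though the
  indicator usually lands within it on compact landscapes.
* The SE treats pairwise resistances as exchangeable (see above).
* TIFF I/O carries georeferencing in a JSON description tag rather than
  full GeoTIFF tags; the ESRI ASCII grid is the interchange format, and
  vector layers travel as GeoJSON.
* Selection distance is planar; inputs are assumed to be in a projected
  CRS with meter-like units.
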