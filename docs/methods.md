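# Methods

This note records the models, numerical choices and limitations behind
`streamhab`, at the level of detail a maintainer or reviewer needs.

## Coordinate conventions

All geometry is planar (x, y) in metres in one projected CRS; z is
elevation in metres. The package never reprojects — every scoring
threshold is metric, so callers must deliver projected coordinates, and
loaders reject files that declare a geographic CRS or whose coordinates
look like longitude/latitude with no declared CRS. "Left" and "right"
banks follow the flow: left is the left-hand side when facing
downstream, resolved by the sign of the cross product of the local
downstream tangent with the vector from the centerline node to the
feature.

## Flight-route planning

* **Sweep spacing.** Δd = 2·h·tan(FOV/2)·(1 − overlap) from a pinhole
  camera model. The overlap targets (75% default, 90% over the
  riparian focus corridor) are the design inputs; the camera FOV is
  configurable (default 84° cross-track, a common consumer-drone
  value).
* **Sweep layout.** Horizontal sweep lines from the south to the north
  edge of the (inset) flight area, evenly spaced at
  extent/(⌈extent/Δd⌉) ≤ Δd; bands intersecting the focus zone are
  subdivided to ≤ Δd_focus. A boundary narrower than Δd gets a single
  line through the middle. Non-convex boundaries yield multiple line
  pieces per row, visited in alternating x-order.
* **Occupancy grid.** 1 m cells by default (resolving the 5 m obstacle
  buffer with a five-cell margin). Blocking is conservative: a cell is
  blocked if it intersects any buffered obstacle at all or is not
  fully inside the boundary. This yields a guarantee used by the
  clearance property: any segment that touches only free cells is
  entirely outside the dilated obstacles, hence ≥ buffer distance from
  the raw obstacle polygons.
* **Detouring.** A blocked segment is replaced by the optimal
  8-connected grid path (diagonal cost √2, no corner cutting) between
  its endpoint cells. The incremental replanning machinery of D*-Lite
  style algorithms is deliberately reduced to a single-shot optimal
  search: the maps are static, and optimality — verified against an
  independent Dijkstra implementation in the test suite — is the
  testable contract. Ties on path length are broken by fewer turns,
  then by heap order over node indices, making results deterministic.
* **Node removal.** Two rules applied to a fixed point: strictly
  collinear interior nodes are dropped, and an interior node is
  dropped when the segment joining its neighbours crosses no blocked
  cell. Nodes joining edges of different classes (survey vs transit)
  are kept so flight-time accounting stays correct. Path length never
  increases and obstacle avoidance is preserved (checked per trial in
  the property tests).
* **Flight time.** Survey and transit lengths divided by their
  class speeds (1 / 2 m/s at low elevation, 4 / 8 m/s at high) plus a
  fixed 30 s liftoff/landing overhead, compared against 75% of the
  20-minute battery endurance.

## Centerline

The medial axis of the bank-bounded channel polygon is approximated by
the Voronoi diagram of boundary points sampled every spacing/2; Voronoi
edges interior to the polygon converge to the true medial axis as the
sampling step shrinks. The skeleton graph is pruned to the
shortest-path (on a tree, the unique path) between the nodes nearest
the inlet and outlet, extended to the inlet/outlet points themselves,
resampled uniformly and arc-length parameterized. Islands are ignored
here (the axis follows the outer banks); they re-enter in the width and
wetted-fraction measurements.

Resolution matters for length-derived quantities: skeleton jitter
inflates arc length. At 1 m node spacing the sinuosity error on
analytic test channels is ≲ 5·10⁻⁴ (about 1.2·10⁻³ at 2 m), so the
parameter-recovery tests resolve the centerline at half the 2 m station
spacing and take every second node as a station.

## Parameter measurement

* **Width W.** The shortest chord through the node between the banks,
  found by sweeping chord orientations at 1° resolution; chords whose
  ends fall on the artificial caps closing the channel polygon (rather
  than on the bank polylines) are rejected, and end stations that admit
  no bank-to-bank chord are skipped. Island crossings are subtracted.
* **Side widths E, B, F.** Measured along the side ray from the node
  through the bank point, extended 100 m past the bank and truncated
  where it would re-enter the stream channel (in a tight meander the
  ray would otherwise measure features of an adjacent limb). Buffer
  and erosion are *contiguous* zones: only the connected run attached
  to the bank (within 0.5 m) counts, because a gap of other land cover
  ends a riparian buffer or an eroded zone by definition. In-stream
  cover sums disjoint patches along the ray, since cover elements are
  naturally patchy.
* **Bank-top width BT.** Distance between the chord line's nearest
  intersections with the left and right bank-top polylines; missing
  intersections flag the value as missing (NaN) rather than zero.
* **Depth D.** Water-surface elevation (constant or per-station
  series) minus bed elevation linearly interpolated in arc length from
  bed points projected onto the centerline. Negative depths are
  clipped to zero and counted.
* **Velocity proxy.** v ∝ Q/(W·D) from continuity, with an arbitrary
  reference discharge; it is used only ordinally (percentile ranks),
  never as a physical velocity.
* **Pools.** A station is pool-flagged iff D is above the 70th
  percentile of stations, the velocity proxy below its 30th percentile,
  and the white-pixel fraction below 0.10. "Slower than 70% of
  stations" is read as the 30th percentile — the mirror of "deeper
  than 70%" — and both percentiles are configurable
  (linear-interpolation definition over the station series). The
  white-water criterion is skipped with a warning when no white
  fractions are supplied. Flagged runs become intervals extended half a
  station spacing at each end; runs separated by less than one spacing
  merge.
* **Coverage (M7).** Fraction of bank arc-length within 2 m (default)
  of the woody-debris layer, via buffered-layer intersection.

## Scoring

The threshold bins are implemented exactly as printed, including the
boundary closures (e.g. buffer ≥ 10 m is excellent but erosion < 0.2 m
is excellent; the bed-form metric M9 is non-monotone with its optimum
in (40, 60)% pools) and both gradient variants for M5 and M7. The
high-gradient sinuosity row duplicates the width/depth thresholds in
the source table; it is implemented as printed and flagged here as a
likely typesetting artifact. The flow-status "excellent = 100%" bin is
a single point; a 10⁻⁹ tolerance absorbs summation roundoff in
length-weighted means. A total score is classified with closures
≥60 / [45,60) / [30,45) / <30; this reproduces both published totals
(43.75 → fair, 47.5 → good), which also fixes the side-averaging rule:
two-sided metrics enter as the mean of the left and right scores.

The site-level category of a spatially continuous metric is the
length-weighted mean parameter value passed through the bins
(`site_category_rule="mean"`); majority-category and worst-category
rules are available, since how a published category distribution maps
to a single site category is not otherwise determined.

Transect mode samples the station series at n equally spaced stations
and uses unweighted means over the samples (bed-form input becomes the
percentage of transects lying in a pool). Vicinity mode reports, per
transect and metric, the worst station category within ±ΔL/2, where ΔL
is the transect spacing; whole-site metrics (M5, M7) keep their site
category. Vicinity categories can never be better than the transect's
own station category, which is tested.

M7 needs bank geometry and a debris layer, which the station table does
not carry; the assessment functions accept them (or a precomputed
site-level coverage percentage) optionally and fall back to 0% —
i.e. "no debris mapped" scores poor, matching how an absent layer
should read.

## Synthetic sites

The generator emulates a delineated single-thread meandering stream:
centerline y = A·sin(2πx/λ), banks offset by ±W(s)/2, piecewise-
constant profiles for width, depth, buffer, erosion and cover built as
offset strips, bed points placed so that D(s) is exact, and a
white-water series that is low inside pool reaches and high outside.
Ground truth is analytic: sinuosity from adaptive quadrature of the
arc-length integrand, bend stations from the analytic heading, expected
metric categories from length-weighted profile means. Everything is
deterministic given the spec; the seed drives only random obstacle
fields.

What it does not emulate: measurement noise, delineation error,
braided or island-split channels (islands are supported as input but
not generated by default), varying water surface slope, and spatially
correlated texture. Passing recovery tests therefore demonstrate
geometric correctness of the measurement chain, not robustness to
digitization noise.

Two regime constraints keep ground truth well-defined: the meander must
not self-intersect (checked, error raised), and side-layer strips must
fit inside the land gap between adjacent meander limbs — if buffer
strips of neighbouring limbs merge, "buffer width of this limb" is no
longer a meaningful quantity and no measurement convention can recover
it. Test fixtures respect both constraints.

Default study conditions for fixtures: 5 m channel width, 0.4 m base
depth with 1.2 m pools, 12 m buffers, 0.35 m cover per side (a value
safely inside a scoring bin; exact bin-edge parameter values make the
expected category undefined under any finite measurement precision),
white-water fractions 0.20 outside / 0.02 inside pools, 2 m station
spacing.

## Known limitations

* Single main channel only; braided networks are out of scope.
* The width sweep costs ~180 polygon intersections per station; at 1°
  angular resolution and 2 m stations a 200 m reach takes a few
  seconds. Coarser `angle_step_deg` trades accuracy for speed.
* The grid search is single-shot; replanning after map updates
  recomputes from scratch.
* GeoJSON is the only vector dialect read and written.
* The channel-gradient input (upstream/downstream bed elevations) is
  taken as given; the package reports both the end-to-end slope and the
  length-weighted mean of per-segment slopes, which coincide by
  telescoping when stations are shared.
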