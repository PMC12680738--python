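# streamhab

Tools for UAV-based stream habitat surveys: obstacle-aware flight-route
planning, spatially continuous extraction of stream habitat parameters
from delineated vector geometries, and multi-metric index (MMI) scoring
of stream habitat health.

It is aimed at freshwater ecologists and restoration practitioners who
delineate stream features (banks, erosion zones, vegetation buffers,
in-stream cover) from drone orthomaps and want reach-scale,
spatially continuous habitat health assessments instead of a handful of
tape-measured transects.

## What it computes

**Route planning.** Obstacles (trees, buildings) are buffered by 5 m
into no-fly zones and the stream channel by 10 m into a focus corridor.
Sweep lines are spaced at

&nbsp;&nbsp;&nbsp;&nbsp;Δd = 2 · h · tan(FOV/2) · (1 − overlap)

for altitude *h* and target cross-track image overlap (75% by default,
90% over the focus corridor), connected into an S-shaped
(boustrophedon) coverage route. Any segment crossing a no-fly zone is
detoured by an optimal 8-connected grid search (diagonal cost √2,
deterministic tie-breaking by turn count), then redundant nodes —
collinear runs and turns whose removal crosses no obstacle — are
removed. Flight time is survey length / survey speed + transit length /
transit speed + 30 s overhead, checked against 75% of a 20-minute
battery.

**Parameter extraction.** The stream centerline is the medial axis of
the bank-bounded channel polygon (Voronoi skeleton of the densified
boundary, pruned to the inlet→outlet path). At each arc-length station
it measures: wetted width *W* (shortest bank-to-bank chord through the
node, island crossings excluded), bank-top width *BT*, per-side erosion
width *E*, vegetation buffer width *B* and in-stream cover width *F*
along side rays, depth *D* (water surface minus interpolated bed
elevation), wetted fraction, and a continuity velocity proxy
v ∝ Q/(W·D). Pools are maximal runs of stations that are deep
(above the 70th depth percentile), slow (below the 30th velocity
percentile) and smooth-surfaced (white-pixel fraction < 10%); bends are
centerline points whose heading change over a 5 m window exceeds 30°.

**MMI scoring.** Nine metrics: channel gradient M1 (selects the high-
vs mild-gradient threshold variants at 0.02 m/m), riparian buffer M2,
bank stability M3, width/depth ratio M4, sinuosity M5, stream flow
status M6, coarse woody debris M7, in-stream cover M8 and channel bed
forms M9. M2–M9 are binned into excellent / good / fair / poor
(scores 10 / 7.5 / 5 / 2.5); two-sided metrics (M2, M3) contribute the
mean of their bank scores. The total (range 20–80) classifies the reach
as excellent (≥60), good ([45,60)), fair ([30,45)) or poor (<30).
Three assessment modes: spatially **continuous** (length-weighted over
all stations), **transect** (n equally spaced stations, emulating a
tape survey) and **vicinity** (worst station category within half a
transect spacing of each transect).

No external data is required: `streamhab.synthetic` generates
sine-meander sites with analytically known widths, depths, sinuosity,
bends, pools and expected metric categories.

## Worked example

`python examples/score_habitat_health.py` builds a 140 m meander with a
pool reach and a 10 m buffer-removal pocket placed *between* two survey
transects, then scores it in all three modes:

```
gradient class M (slope 0.0023 m/m)
metric    continuous    transect
M2             10.00       10.00
M3             10.00       10.00
M4              7.50        7.50
M5              5.00        5.00
M6             10.00       10.00
M7              2.50        2.50
M8             10.00       10.00
M9              5.00        2.50
total          60.00       57.50
overall: continuous=excellent, transect=good

left-bank buffer pocket: continuous poor fraction 6.8%; vicinity
per-transect worst M2-left: ['excellent', ..., 'poor', 'poor', ..., 'excellent']
```

The transect mode misses the impairment entirely (its M2 site value is
the mean over 14 stations that all fall outside the pocket) and also
underestimates the pool fraction (M9 scores 2.5 instead of 5 because
only one transect lands in the pool). The continuous mode sees a 6.8%
poor fraction on the left bank, and the vicinity mode pins it to the
two transects flanking the pocket.

The other examples cover route planning
(`examples/plan_survey_route.py`), parameter extraction with pool/bend
recovery (`examples/extract_habitat_parameters.py`) and synthetic site
generation (`examples/generate_synthetic_site.py`). A thin CLI mirrors
them: `streamhab plan-route | extract-params | assess | simulate`.

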