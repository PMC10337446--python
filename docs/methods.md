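# Methods

This note records the model, the parameter choices, the numerical
conventions, and the deliberate design decisions behind the package, in
the spirit of a statistical software vignette. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and coordinate conventions

An EMA event is a `(participant_id, timestamp_utc, x, y, kind)` record
with `kind ∈ {smoking, nonsmoking}`. Coordinates are consumed **already
projected** in a planar US-feet system (the study area uses a NAD83
state-plane zone in US feet); the package is otherwise CRS-agnostic and
performs no geographic reprojection. Meters are converted at
1 m = 3.28083333 US survey ft, pinned as a named constant
(`US_SURVEY_FEET_PER_METER`): the source projection never states whether
the US-survey or international foot applies, the ~0.0006% difference is
immaterial at these scales, but the choice is explicit rather than silent.

Timestamps are stored in UTC. Local time is derived by a **fixed
configured offset** (default −8, Pacific standard time), not a tz
database: fixed offsets keep fixtures and replays deterministic, and
daylight-saving handling is explicitly the caller's responsibility through
the offset. The day is divided into eight half-open 3-hour bins
[0,3), [3,6), …, [21,24); half-open intervals avoid gaps at bin edges even
though events carry second resolution.

## Cleaning: the 5-minute duplicate rule

Smoking reports arriving in quick succession are overwhelmingly double
reports or app glitches, so a smoking event is retained iff it is at least
5 minutes (configurable) after the most recently **retained** smoking
event — greedy keep-first in chronological order. Comparing against the
last retained report (not any prior raw report) means a burst of reports
3 minutes apart collapses to roughly one report per window instead of
dropping the whole chain after the first. Keep-first is the default
because it is deterministic and the earliest report of a burst is the
closest to the actual lighting-up moment; a keep-last variant is exposed
(`dedup_keep="last"`) for sensitivity checks. Nonsmoking events are never
dropped. The rule is idempotent and commutes with the timezone shift, so
its position before binning is a convention, not a constraint.

## Kernel density surface

The risk surface is a quartic (biweight) kernel sum,
f(g) = Σ_{d<τ} (3/πτ²)(1 − d²/τ²)², evaluated at the centers of square
raster cells. The quartic form is the kernel used by the standard GIS
kernel-density tools this workflow descends from; it is currently the only
kernel, and the parameter object records it so alternates can be added
without changing contracts. Defaults: bandwidth τ = 1320 ft (0.25 mi, a
comfortable walking distance — the scale at which a person's "smoking
spot" extends) and 150-ft cells, both interpreted as lengths (a cell
*side* of 150 ft; an area reading of "150 sq ft" would give implausible
12-ft cells). Units are events/ft²; no areal scaling factor is applied
because the downstream min-max normalization cancels any constant.

The grid covers the event bounding box padded by τ on every side, with the
origin snapped down to a cell multiple (so shifted-but-snapped event sets
produce congruent grids). Padding guarantees the surface decays to zero
inside the raster, which in turn pins the normalization minimum to 0 in
practice. Evaluation is a per-event bounding-box loop, O(events × cells
within τ): at the scale the pipeline targets (tens to a few hundred
events per participant) a spatial index would be pure overhead. Rasters
round-trip through Esri ASCII grids for portability.

## Zones, zonal means, and the missing-zone mechanism

A zone's score is the arithmetic mean of raster values at the cell centers
falling inside it. Point-in-zone assignment is **half-open up-and-right**:
a point on a shared edge belongs to the zone whose interior lies toward
+x/+y, implemented by nudging the query point by 10⁻⁶ ft before a strict
interior test (far below zone scales, far above float64 resolution at
state-plane magnitudes). Every point therefore belongs to exactly one zone
of a partition — cell centers for zonal means, and event locations for
geofence selection, use the same rule.

A zone containing no cell center gets a **missing** mean: this reproduces,
mechanically, the real phenomenon of narrow roadway blocks that are
smaller than the raster cell and "do not rasterize". Missing zones are
excluded from normalization, terciles, and geofences, but counted and
logged, because an excluded zone may well be a genuine risk location — the
fishnet designs exist partly to eliminate this failure mode. Zones wholly
outside the raster extent are likewise missing rather than zero: the
normalization universe is the set of zones the participant's surface
actually covers.

Min-max normalization maps non-missing means to [0, 1] and rounds to 6
decimals (configurable). Rounding is semantically load-bearing: a raw norm
of 0.9999984 becomes 0.999998 and is excluded by a threshold of 1.0, which
is why full-threshold sweeps can legitimately return empty geofences. If
all means are equal the convention is norm = 1 for every zone (a uniform
surface means every zone is the hotspot; mapping to 0 would silently
discard the participant).

Retention is **inclusive** (norm ≥ threshold): where the source method's
prose wavers between "above" and "greater than or equal to", the explicit
inequality wins. Retained zones are ranked into terciles by equal counts
(remainders to the lower groups, e.g. 7 → 3/2/2) rather than by value
range — the standard reading of "tercile" — with boundary ties demoted to
the lower group so equal risk never straddles two labels; a value-range
mode would only affect map styling, not geofences, and was left out of v1.

### Synthetic census blocks

Real census blocks are not bundled (they would require external
downloads); irregular partitions are emulated by Voronoi tessellations of
uniform seeds, made finite by mirroring seeds across the extent edges and
clipping. A configurable fraction of cells is split by a 20-ft-wide
corridor through the centroid — the width of a residential road, well
under a raster cell — whose pieces become separate zones; the corridors
supply the non-rasterizing slivers described above while conserving total
area. The GeoJSON reader accepts externally prepared block polygons for
real-data use.

## Geofence construction

Per 3-hour bin a zone contributes iff (1) its norm passes the threshold —
risk is computed from the participant's *entire* smoking history, so it is
time-of-day-invariant — and (2) at least one of the bin's smoking events
falls inside the zone. Time stratification enters only through condition
(2): a zone can be fenced in the evening but not the morning purely
because the participant never smokes there in the morning. The contributed
zones are unioned (zones sharing any boundary point — edge or corner —
merge, making the rook/queen adjacency question moot), buffered outward by
100 m with round joins at 32 segments per quarter circle (recorded in the
configuration because fence area depends on it), and dissolved, so
disjoint groups whose buffers overlap also fuse. An alternative reading —
requiring the event only inside the final buffered fence rather than the
zone — would retain slightly more zones; the zone reading matches
"high-risk zones were identified" semantics and is the one implemented.

Events exactly on a fence boundary count as captured (closure convention):
a device entering the perimeter should trigger.

## Evaluation

Capture rate is in-sample by design — the fences are scored on the same
30-day events that built them, matching the study design the package
emulates; a held-out mode is a possible extension, not a v1 feature.
Per-bin percentages use 1 decimal; bins with no smoking events report NA
and are excluded from across-bin averages. Because the weighting of an
"average across 3-hour periods" is ambiguous, both the unweighted
across-bin mean and the event-weighted pooled percentage are available.
The threshold sweep (0.1–0.9 by default) uses time-independent fences;
retention shrinks monotonically with the threshold, so capture is
non-increasing — asserted directly in tests. The partition comparison
ranks block/fishnet designs per bin and overall (dense ranks, ties
reported) and carries total geofenced area, since equal capture from a
much larger fence means more intrusive triggering.

## Synthetic participants

The generator is an anchors-and-background mixture — the minimal process
that produces both regimes the method must face: people who smoke at a few
habitual places, and people who frequently smoke in new locations. Each
event draws a 3-hour bin from a diurnal profile (default mass
concentrated from mid-morning to midnight), an anchor from that bin's
anchor weights, and a position from the anchor's isotropic Gaussian
scatter (default 200 ft — a parking lot or back porch, small relative to
τ); with probability `dispersion` the position is instead uniform over the
extent. Daily smoking counts are Poisson; nonsmoking surveys are Poisson
capped at 3/day, mirroring prompt-limited EMA designs. A configurable
duplicate rate injects double smoking reports under 5 minutes apart to
exercise the cleaning stage. Timestamps are whole seconds, as a phone app
would log.

The four-case suite calibrates rates to the emulated study's compliance
quartiles — deduplicated smoking totals within [12, 177] and nonsmoking
within [8, 67] over 30 days on a 20,000-ft-square extent — with three
clustered cases (dispersion 0.03) and one heavy, dispersed case
(dispersion 0.55, two anchors), whose event mass concentrated in its two
busiest blocks is deliberately smaller than any clustered case's. Each
case redraws with a derived sub-seed until its realized totals land in
range (the margins make this a handful of draws). The suite emits the
shared block, 500-ft, and 1000-ft fishnet partitions covering the extent.

What the generator does *not* emulate: mobility trajectories between
events, GPS measurement error and urban-canyon bias, road networks,
location-dependent EMA compliance, and within-day autocorrelation of
smoking beyond the diurnal profile. Passing tests therefore demonstrate
that the pipeline recovers planted spatial structure and reproduces the
method's qualitative trade-offs (clustered ≫ dispersed capture;
block-sliver rasterization failures; threshold monotonicity), not that
real-world capture rates will match any particular number.

## Problem sizes and determinism

Default test and demonstration runs use 4 participants × 30 days
(≈ 20–240 events each), rasters of roughly 150×150 cells, and partitions
of 10²–10³ zones — the same order as the emulated study's per-participant
workload, and comfortably interactive. All stochastic stages consume
`numpy.random.default_rng` generators seeded explicitly; identical seeds
and configurations reproduce byte-identical stage outputs (buffer
discretization included), which the pipeline manifest's file digests make
checkable.

## Known limitations

- Fixed bandwidth: a single τ over-smooths dense downtown clusters and
  under-smooths sprawl; adaptive and space-time kernels are natural
  extensions and deliberately out of scope.
- In-sample evaluation bounds optimism from above; no cross-validation.
- A fixed UTC offset misassigns bins within ±1 h around DST transitions
  unless the caller splits the stream.
- Zone risk ignores population or visit-frequency denominators; it is a
  density of reports, not a rate per exposure time.
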