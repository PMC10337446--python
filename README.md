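# geofence-kde

Person-specific, time-stratified geofences for just-in-time smoking
cessation support, built from ecological momentary assessment (EMA) data:
GPS-tagged, timestamped self-reports of smoking and nonsmoking events
collected on a smartphone over 30 days.

The package answers a practical intervention-design question: *where and
when* should a cessation app draw the virtual perimeters that trigger a
supportive message? It does so by estimating each participant's spatial
smoking-risk surface, scoring candidate zones, and drawing buffered
geofences separately for each 3-hour interval of the day — then measuring
how many of the participant's smoking events the geofences would have
captured, and how that capture rate trades off against geofence size across
risk thresholds and zone designs (irregular census-block-like polygons
versus uniform fishnet grids).

## Method

For one participant, with planar coordinates in US feet:

1. **Cleaning.** Smoking reports within 5 minutes of the last retained
   smoking report are dropped as double reports. Timestamps are shifted
   from UTC to local time by a fixed offset and binned into eight 3-hour
   intervals [0,3), [3,6), …, [21,24).
2. **Density surface.** The smoking events are smoothed with a
   compact-support quartic kernel of bandwidth τ = 1320 ft (a quarter
   mile), evaluated on a 150-ft raster:

   f(g) = Σ_{i : d_ig < τ} (3 / πτ²) (1 − d²_ig / τ²)²,

   where d_ig is the distance from grid point g to event i. The weight is
   exactly zero at distance τ.
3. **Zonal risk.** The raster is averaged over each zone of a partition
   (blocks, 500-ft fishnet, or 1000-ft fishnet), min-max normalized to
   [0, 1] (rounded to 6 decimals), and zones at or above a threshold
   (default 0.3) are ranked into low/medium/high risk terciles. Zones too
   small or narrow to contain a raster cell center fail to rasterize and
   are reported as missing — a real failure mode of roadway-sliver blocks.
4. **Geofences.** Per 3-hour bin, zones that pass the threshold *and*
   contain at least one of that bin's smoking events are unioned, buffered
   outward by 100 m (round joins), and dissolved into one multipolygon.
5. **Evaluation.** Capture rate = percent of smoking events inside their
   own bin's geofence (in-sample, as in the underlying study design; above
   80% is considered good, above 50% adequate), plus a time-independent
   variant, a 0.1–0.9 threshold sensitivity sweep, and a cross-partition
   ranking that also reports total geofenced area — equal capture can come
   from very differently sized fences.

Because the study's raw GPS traces are not public, the package ships a
first-class synthetic generator (`geofence_kde.synthgen`) producing
four participants along EMA-compliance quartiles — three spatially
clustered around anchor locations, one heavy reporter with most events
dispersed across the map — plus the three shared zone partitions.

## Worked example

```
geofence-kde demo --seed 7 --out demo/
```

generates the four synthetic cases and runs every stage against all three
partitions. For the lightest-reporting case it prints:

```
q25: {"n_events_raw": 29, "n_events_clean": 28, "n_duplicates_dropped": 1,
      "n_smoking_events": 19, "n_zones_blocks": 156, "n_fences_blocks": 7,
      "n_zones_fishnet_500": 1600, "n_fences_fishnet_500": 6,
      "n_zones_fishnet_1000": 400, "n_fences_fishnet_1000": 6}
```

— one duplicate smoking report was dropped, 19 smoking events remained,
and non-empty geofences were built for 7 of the 8 three-hour bins on the
block partition. `demo/q25/capture_fishnet_1000.csv` then holds the
per-bin scores:

```
bin,n_smoking,n_captured,pct_captured
00:00-02:59,1,1,100.0
03:00-05:59,0,0,
...
overall,19,15,78.9
```

(the 03:00–05:59 bin has no smoking events, so its percentage is empty and
it is excluded from across-bin averages), and `demo/q25/sweep_blocks.csv`
shows the threshold trade-off — at threshold 0.3 the time-independent
block geofences capture 100.0% of the 19 events over 25.6 million sq ft;
at 0.9 capture drops to 63.2% over 8.2 million sq ft.

The same stages are available piecemeal (`preprocess`, `kde`, `fishnet`,
`blocks`, `run`) and as library functions.

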