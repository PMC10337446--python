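"""Per-3-hour-interval geofence construction.

For each 3-hour local-time bin, a zone contributes to the geofence iff

1. its normalized mean KDE is at or above the retention threshold
   (risk is computed from ALL of the participant's smoking events, so it is
   the same across bins), and
2. at least one of the bin's smoking events falls inside the zone.

Contributing zones are unioned (so zones sharing any boundary point merge
into one group), buffered outward by 100 m with round joins, and dissolved
into one multipolygon per bin. A bin with no qualifying zone gets an empty
geofence.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from shapely.geometry import MultiPolygon, mapping, shape
from shapely.ops import unary_union

from geofence_kde.core_io import (
    US_SURVEY_FEET_PER_METER,
    PartitionKind,
    TimeBin,
    ZonePartition,
)
from geofence_kde.preprocess import BinnedEvent
from geofence_kde.zoning import MISSING, ZoneRiskTable, assign_points

EMPTY = MultiPolygon([])


@dataclasses.dataclass
class GeofenceSet:
    """Per-bin geofence multipolygons plus the zones that produced them."""

    participant_id: str
    partition_kind: PartitionKind
    threshold: float
    fences: dict[TimeBin, MultiPolygon]
    contributing: dict[TimeBin, list[str]]

    def fence(self, bin: TimeBin) -> MultiPolygon:
        return self.fences.get(bin, EMPTY)

    @property
    def total_area_ft2(self) -> float:
        """Area of the union of all bins' fences (a bin-overlap-free total)."""
        return unary_union(list(self.fences.values())).area

    def to_geojson(self, path: str | Path) -> None:
        doc = {
            "type": "FeatureCollection",
            "participant_id": self.participant_id,
            "partition_kind": self.partition_kind.value,
            "threshold": self.threshold,
            "features": [
                {
                    "type": "Feature",
                    "properties": {
                        "bin_index": b.index,
                        "partition_kind": self.partition_kind.value,
                        "threshold": self.threshold,
                        "contributing_zones": self.contributing.get(b, []),
                    },
                    "geometry": mapping(self.fences[b]),
                }
                for b in sorted(self.fences, key=lambda b: b.index)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
            fh.write("\n")

    @classmethod
    def from_geojson(cls, path: str | Path) -> "GeofenceSet":
        with open(path) as fh:
            doc = json.load(fh)
        fences, contributing = {}, {}
        for feat in doc["features"]:
            b = TimeBin(feat["properties"]["bin_index"])
            geom = shape(feat["geometry"])
            if geom.geom_type == "Polygon":
                geom = MultiPolygon([geom])
            fences[b] = geom
            contributing[b] = list(feat["properties"].get("contributing_zones", []))
        return cls(
            doc.get("participant_id", ""),
            PartitionKind(doc.get("partition_kind", "custom")),
            float(doc.get("threshold", 0.0)),
            fences,
            contributing,
        )


def select_zones(
    risk: ZoneRiskTable,
    partition: ZonePartition,
    smoking_events: Sequence[BinnedEvent],
    threshold: float,
) -> list[str]:
    """Zones with norm >= threshold containing >= 1 of the given smoking events.

    Events are assigned to zones with the same half-open boundary rule as
    zonal statistics, so a report on a shared edge counts for exactly one
    zone. Zones with a MISSING norm never qualify.
    """
    if not smoking_events:
        return []
    xs = [b.event.x for b in smoking_events]
    ys = [b.event.y for b in smoking_events]
    hit = {z for z in assign_points(partition, xs, ys) if z is not None}
    out = []
    for zone in partition.zones:
        norm = risk.norm(zone.zone_id) if zone.zone_id in risk.rows else MISSING
        if norm is not MISSING and norm >= threshold and zone.zone_id in hit:
            out.append(zone.zone_id)
    return out


def _buffered_union(
    zone_ids: Iterable[str],
    partition: ZonePartition,
    buffer_ft: float,
    quad_segs: int,
) -> MultiPolygon:
    ids = list(zone_ids)
    if not ids:
        return EMPTY
    union = unary_union([partition.zone(z).polygon for z in ids])
    fused = unary_union(union.buffer(buffer_ft, quad_segs=quad_segs))
    if fused.geom_type == "Polygon":
        fused = MultiPolygon([fused])
    return fused


def build_geofences(
    selected: Mapping[TimeBin, Sequence[str]],
    partition: ZonePartition,
    buffer_m: float = 100.0,
    participant_id: str = "",
    threshold: float = 0.3,
    quad_segs: int = 32,
) -> GeofenceSet:
    """Union each bin's selected zones, buffer by ``buffer_m``, dissolve.

    The buffer distance is converted to US feet; round joins are discretized
    with ``quad_segs`` segments per quarter circle (the fence area depends on
    this, hence it is part of the configuration). Buffers of disjoint zone
    groups that overlap are dissolved into one polygon.
    """
    if buffer_m <= 0:
        raise ValueError("buffer_m must be positive")
    buffer_ft = buffer_m * US_SURVEY_FEET_PER_METER
    fences: dict[TimeBin, MultiPolygon] = {}
    contributing: dict[TimeBin, list[str]] = {}
    for b in sorted(selected, key=lambda b: b.index):
        ids = sorted(selected[b])
        fences[b] = _buffered_union(ids, partition, buffer_ft, quad_segs)
        contributing[b] = ids
    return GeofenceSet(participant_id, partition.partition_kind, threshold, fences, contributing)


def build_time_independent_fence(
    risk: ZoneRiskTable,
    partition: ZonePartition,
    smoking_events: Sequence[BinnedEvent],
    threshold: float,
    buffer_m: float = 100.0,
    quad_segs: int = 32,
) -> tuple[MultiPolygon, list[str]]:
    """One geofence ignoring time of day: the smoking-event condition is
    evaluated against the participant's full smoking stream."""
    ids = select_zones(risk, partition, smoking_events, threshold)
    fence = _buffered_union(
        ids, partition, buffer_m * US_SURVEY_FEET_PER_METER, quad_segs
    )
    return fence, ids
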