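"""Domain types and file I/O shared by every pipeline stage.

Coordinates are planar US feet throughout (the study projection is a NAD83
state-plane zone in US feet; reprojection from geographic coordinates happens
upstream of this package, which is otherwise CRS-agnostic). Timestamps are
stored in UTC; local time is derived with a fixed configured offset.

Formats:

* events — CSV with header ``participant_id,timestamp_utc,x,y,kind``;
  timestamps ISO-8601 with an explicit ``Z``;
* zone partitions and geofences — GeoJSON FeatureCollections whose
  coordinates are already in the planar feet system;
* density rasters — Esri ASCII grid (see :mod:`geofence_kde.kde`);
* pipeline configuration — a flat JSON object mirroring
  :class:`PipelineConfig` field names.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.validation import make_valid

log = logging.getLogger("geofence_kde")

#: US survey feet per meter (1 m = 3937/1200 survey ft). The study CRS is a
#: NAD83 state-plane zone in US feet; the ~0.0006% difference from the
#: international foot is immaterial at these scales but is pinned here rather
#: than guessed silently wherever meters are converted.
US_SURVEY_FEET_PER_METER = 3.28083333

EVENT_COLUMNS = ("participant_id", "timestamp_utc", "x", "y", "kind")


class ConfigError(ValueError):
    """A configuration or file-structure problem (missing column, bad value)."""


class RowError(ValueError):
    """One or more malformed data rows; carries (row_number, message) pairs."""

    def __init__(self, rows: Sequence[tuple[int, str]]):
        self.rows = list(rows)
        detail = "; ".join(f"row {n}: {msg}" for n, msg in self.rows)
        super().__init__(f"{len(self.rows)} malformed row(s): {detail}")


class EventKind(str, Enum):
    smoking = "smoking"
    nonsmoking = "nonsmoking"


@dataclasses.dataclass(frozen=True)
class EmaEvent:
    """One timestamped, georeferenced smoking or nonsmoking self-report."""

    participant_id: str
    timestamp_utc: datetime
    x: float  # planar, US feet
    y: float  # planar, US feet
    kind: EventKind

    def __post_init__(self) -> None:
        if self.timestamp_utc.tzinfo is None:
            object.__setattr__(
                self, "timestamp_utc", self.timestamp_utc.replace(tzinfo=timezone.utc)
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")
        if not isinstance(self.kind, EventKind):
            object.__setattr__(self, "kind", EventKind(self.kind))


@dataclasses.dataclass(frozen=True)
class TimeBin:
    """One of the eight contiguous 3-hour local-time intervals of a day."""

    index: int  # 0..7

    def __post_init__(self) -> None:
        if not 0 <= self.index <= 7:
            raise ValueError(f"bin index {self.index} outside 0..7")

    @property
    def start_hour(self) -> int:
        return 3 * self.index

    @property
    def label(self) -> str:
        return f"{self.start_hour:02d}:00-{self.start_hour + 2:02d}:59"

    @classmethod
    def for_hour(cls, local_hour: int) -> "TimeBin":
        return cls(local_hour // 3)


ALL_BINS = tuple(TimeBin(i) for i in range(8))


@dataclasses.dataclass(frozen=True)
class Zone:
    """An identified polygon of a zone partition (block or fishnet cell)."""

    zone_id: str
    polygon: Polygon | MultiPolygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValueError(f"zone {self.zone_id!r}: invalid polygon")
        if self.polygon.area <= 0:
            raise ValueError(f"zone {self.zone_id!r}: non-positive area")


class PartitionKind(str, Enum):
    blocks = "blocks"
    fishnet_500 = "fishnet_500"
    fishnet_1000 = "fishnet_1000"
    custom = "custom"


@dataclasses.dataclass
class ZonePartition:
    """A tessellation of the study extent into pairwise interior-disjoint zones."""

    partition_kind: PartitionKind
    zones: list[Zone]

    def __post_init__(self) -> None:
        self.partition_kind = PartitionKind(self.partition_kind)
        ids = [z.zone_id for z in self.zones]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ConfigError(f"duplicate zone_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.zones)

    def __iter__(self):
        return iter(self.zones)

    def zone(self, zone_id: str) -> Zone:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z
        raise KeyError(zone_id)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        xs0, ys0, xs1, ys1 = zip(*(z.polygon.bounds for z in self.zones))
        return (min(xs0), min(ys0), max(xs1), max(ys1))


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline, with the study defaults.

    bandwidth_ft
        Kernel search radius tau; contributions vanish at this distance.
        Default 1320 ft (a quarter mile, a comfortable walking distance).
    cell_size_ft
        Side length of the square density-raster cells. Default 150 ft.
    threshold
        Normalized mean-KDE cutoff for retaining a zone as high-risk
        (inclusive, >=). Default 0.3.
    buffer_m
        Outward buffer around grouped high-risk zones, meters. Default 100.
    dedup_window_min
        Smoking reports closer than this to the last retained smoking report
        are dropped as double reports. Default 5 minutes.
    normalization_decimals
        Rounding applied to normalized mean KDE values. Default 6.
    utc_offset_hours
        Fixed offset adding to UTC to obtain local time (Pacific standard
        time is -8). Daylight-saving handling is the caller's responsibility.
    dedup_keep
        "first" (default) keeps the earliest report of a burst; "last" is
        exposed for sensitivity checks.
    buffer_quad_segs
        Segments per quarter circle when discretizing round buffer joins;
        geofence area depends on it, so it is pinned in config. Default 32.
    """

    bandwidth_ft: float = 1320.0
    cell_size_ft: float = 150.0
    threshold: float = 0.3
    buffer_m: float = 100.0
    dedup_window_min: float = 5.0
    normalization_decimals: int = 6
    utc_offset_hours: float = -8.0
    dedup_keep: str = "first"
    buffer_quad_segs: int = 32

    def __post_init__(self) -> None:
        if self.bandwidth_ft <= 0:
            raise ConfigError("bandwidth_ft must be positive")
        if self.cell_size_ft <= 0:
            raise ConfigError("cell_size_ft must be positive")
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigError("threshold must lie in [0, 1]")
        if self.buffer_m <= 0:
            raise ConfigError("buffer_m must be positive")
        if self.dedup_window_min <= 0:
            raise ConfigError("dedup_window_min must be positive")
        if self.normalization_decimals < 0:
            raise ConfigError("normalization_decimals must be >= 0")
        if self.dedup_keep not in ("first", "last"):
            raise ConfigError("dedup_keep must be 'first' or 'last'")

    @property
    def buffer_ft(self) -> float:
        return self.buffer_m * US_SURVEY_FEET_PER_METER

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Event CSV I/O


def _parse_timestamp(text: str) -> datetime:
    ts = datetime.fromisoformat(text.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def read_events(path: str | Path) -> list[EmaEvent]:
    """Read an event table, validating every row.

    Raises :class:`ConfigError` for a missing header column and
    :class:`RowError` listing each offending row (1-based data row numbers)
    for unparseable timestamps, coordinates, or event kinds.
    """
    events: list[EmaEvent] = []
    bad: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(EVENT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ConfigError(f"{path}: missing column(s) {sorted(missing)}")
        for n, row in enumerate(reader, start=1):
            try:
                ts = _parse_timestamp(row["timestamp_utc"])
            except ValueError:
                bad.append((n, f"unparseable timestamp {row['timestamp_utc']!r}"))
                continue
            try:
                x, y = float(row["x"]), float(row["y"])
                if not (math.isfinite(x) and math.isfinite(y)):
                    raise ValueError
            except ValueError:
                bad.append((n, f"unparseable coordinates ({row['x']!r}, {row['y']!r})"))
                continue
            try:
                kind = EventKind(row["kind"])
            except ValueError:
                bad.append(
                    (n, f"invalid kind {row['kind']!r} (expected 'smoking' or 'nonsmoking')")
                )
                continue
            events.append(EmaEvent(row["participant_id"], ts, x, y, kind))
    if bad:
        raise RowError(bad)
    return events


def write_events(events: Iterable[EmaEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            ts = e.timestamp_utc.astimezone(timezone.utc)
            fmt = "%Y-%m-%dT%H:%M:%S.%f" if ts.microsecond else "%Y-%m-%dT%H:%M:%S"
            writer.writerow(
                [
                    e.participant_id,
                    ts.strftime(fmt) + "Z",
                    repr(e.x),
                    repr(e.y),
                    e.kind.value,
                ]
            )


# ---------------------------------------------------------------------------
# Partition GeoJSON I/O

#: Interior overlap between two zones above this fraction of the smaller
#: zone's area is a partition error; below it is treated as shared-boundary
#: noise from upstream digitizing.
OVERLAP_TOLERANCE = 1e-6


def _as_polygon(geom, zone_id: str) -> Polygon | MultiPolygon:
    if not geom.is_valid:
        repaired = make_valid(geom)
        if repaired.geom_type in ("Polygon", "MultiPolygon") and repaired.is_valid:
            log.warning("zone %s: repaired invalid polygon", zone_id)
            geom = repaired
        else:
            raise ConfigError(f"zone {zone_id!r}: invalid polygon could not be repaired")
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise ConfigError(f"zone {zone_id!r}: non-polygon geometry {geom.geom_type}")
    return geom


def read_partition(path: str | Path) -> ZonePartition:
    """Read a GeoJSON FeatureCollection of polygon zones.

    Each feature needs a ``zone_id`` property; coordinates must already be in
    the planar feet system. Trivially invalid polygons are repaired; interior
    overlaps exceeding ``OVERLAP_TOLERANCE`` of the smaller zone are an error.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ConfigError(f"{path}: not a GeoJSON FeatureCollection")
    kind = doc.get("partition_kind", PartitionKind.custom.value)
    zones: list[Zone] = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if "zone_id" not in props:
            raise ConfigError(f"{path}: feature without a zone_id property")
        zone_id = str(props["zone_id"])
        geom = _as_polygon(shape(feat["geometry"]), zone_id)
        zones.append(Zone(zone_id, geom))
    part = ZonePartition(PartitionKind(kind), zones)
    _check_interior_disjoint(part)
    return part


def _check_interior_disjoint(part: ZonePartition) -> None:
    from shapely.strtree import STRtree

    polys = [z.polygon for z in part.zones]
    tree = STRtree(polys)
    for i, poly in enumerate(polys):
        for j in tree.query(poly, predicate="intersects"):
            if j <= i:
                continue
            inter = poly.intersection(polys[j])
            if inter.is_empty or inter.area == 0:
                continue
            smaller = min(poly.area, polys[j].area)
            if inter.area > OVERLAP_TOLERANCE * smaller:
                raise ConfigError(
                    f"zones {part.zones[i].zone_id!r} and {part.zones[j].zone_id!r} "
                    f"overlap by {inter.area:.6g} sq ft "
                    f"({inter.area / smaller:.2%} of the smaller zone)"
                )


def write_partition(part: ZonePartition, path: str | Path) -> None:
    doc = {
        "type": "FeatureCollection",
        "partition_kind": part.partition_kind.value,
        "features": [
            {
                "type": "Feature",
                "properties": {"zone_id": z.zone_id},
                "geometry": mapping(z.polygon),
            }
            for z in part.zones
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")
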