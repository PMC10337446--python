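"""Zone partitions, zonal mean KDE, min-max normalization, risk terciles.

A *zone partition* tessellates the study extent into identified polygons:
either uniform fishnet grid cells or irregular census-block-like polygons
(emulated here by clipped Voronoi cells, optionally split by narrow roadway
corridors). Each zone's risk score is the arithmetic mean of density-raster
values at the cell centers falling inside it, min-max normalized to [0, 1]
across the participant's zones and rounded to a configured number of
decimals. Zones at or above the retention threshold are ranked into
low/medium/high terciles.

A zone too small or narrow to contain any raster cell center gets no mean
(``MISSING``): this reproduces the rasterization failure of real roadway
slivers, which are excluded from risk classification but counted and
logged.

Point-to-zone assignment is half-open: a point on a shared edge belongs to
the zone whose interior lies up-and-right, so every point belongs to
exactly one zone of a partition. Implemented by nudging the query point by
a sub-microfoot epsilon in +x/+y before a strict interior test.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box
from shapely.strtree import STRtree

from geofence_kde.core_io import PartitionKind, Zone, ZonePartition
from geofence_kde.kde import DensityRaster

log = logging.getLogger("geofence_kde")

#: Sentinel for a zone with no raster cell center (did not rasterize).
MISSING = None

#: Nudge applied before point-in-zone tests to realize the half-open
#: up-and-right boundary rule. Far below raster/zone scales (>= tens of
#: feet) and far above float64 resolution at state-plane magnitudes (~1e-9).
_EPS = 1e-6


class Tercile(str, Enum):
    low = "low"
    medium = "medium"
    high = "high"
    not_retained = "not_retained"
    missing = "missing"


@dataclasses.dataclass(frozen=True)
class RiskRow:
    mean_kde: Optional[float]
    norm_mean_kde: Optional[float]
    tercile: Tercile


@dataclasses.dataclass
class ZoneRiskTable:
    """Per-zone mean KDE, normalized value, and tercile class."""

    partition_kind: PartitionKind
    rows: dict[str, RiskRow]

    @property
    def n_missing(self) -> int:
        return sum(1 for r in self.rows.values() if r.mean_kde is MISSING)

    def retained(self) -> list[str]:
        return [
            z
            for z, r in self.rows.items()
            if r.tercile in (Tercile.low, Tercile.medium, Tercile.high)
        ]

    def norm(self, zone_id: str) -> Optional[float]:
        return self.rows[zone_id].norm_mean_kde

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("zone_id,mean_kde,norm_mean_kde,tercile\n")
            for zone_id, r in self.rows.items():
                mean = "" if r.mean_kde is MISSING else repr(r.mean_kde)
                norm = "" if r.norm_mean_kde is MISSING else repr(r.norm_mean_kde)
                fh.write(f"{zone_id},{mean},{norm},{r.tercile.value}\n")

    @classmethod
    def from_csv(cls, path, partition_kind=PartitionKind.custom) -> "ZoneRiskTable":
        rows: dict[str, RiskRow] = {}
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            if header != ["zone_id", "mean_kde", "norm_mean_kde", "tercile"]:
                raise ValueError(f"{path}: unexpected risk-table header {header}")
            for line in fh:
                zone_id, mean, norm, terc = line.rstrip("\n").split(",")
                rows[zone_id] = RiskRow(
                    MISSING if mean == "" else float(mean),
                    MISSING if norm == "" else float(norm),
                    Tercile(terc),
                )
        return cls(PartitionKind(partition_kind), rows)


# ---------------------------------------------------------------------------
# Partition generators


def make_fishnet(
    extent: tuple[float, float, float, float],
    cell_side: float,
    partition_kind: PartitionKind | str | None = None,
) -> ZonePartition:
    """Tile ``extent`` (xmin, ymin, xmax, ymax) with square cells.

    The grid anchors at the extent's lower-left corner snapped down to a
    multiple of ``cell_side`` and extends far enough to cover the extent, so
    the union of cells is a superset of the extent with no gaps or overlaps.
    Zone ids encode the (row, col) position.
    """
    if cell_side <= 0:
        raise ValueError("cell_side must be positive")
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate extent")
    x0 = math.floor(xmin / cell_side) * cell_side
    y0 = math.floor(ymin / cell_side) * cell_side
    n_cols = math.ceil((xmax - x0) / cell_side)
    n_rows = math.ceil((ymax - y0) / cell_side)
    if partition_kind is None:
        partition_kind = {
            500.0: PartitionKind.fishnet_500,
            1000.0: PartitionKind.fishnet_1000,
        }.get(float(cell_side), PartitionKind.custom)
    zones = [
        Zone(
            f"r{r}_c{c}",
            box(x0 + c * cell_side, y0 + r * cell_side,
                x0 + (c + 1) * cell_side, y0 + (r + 1) * cell_side),
        )
        for r in range(n_rows)
        for c in range(n_cols)
    ]
    return ZonePartition(PartitionKind(partition_kind), zones)


def make_pseudo_blocks(
    extent: tuple[float, float, float, float],
    n_seeds: int,
    rng_seed: int,
    sliver_fraction: float = 0.0,
    corridor_width: float = 20.0,
) -> ZonePartition:
    """Census-block-like irregular partition: clipped Voronoi cells.

    Seeds are sampled uniformly over the extent; their Voronoi tessellation
    (finite everywhere thanks to mirrored ghost seeds) is clipped to the
    extent box. Real census blocks include very small, narrow blocks along
    roadways that fail to rasterize at typical density-cell sizes; to
    reproduce that failure mode, a ``sliver_fraction`` of the cells is split
    by a narrow corridor (default 20 ft, the width of a residential road and
    well under a 150-ft raster cell), the corridor becoming its own
    roadway-sliver zone. Areas are conserved:
    zone areas always sum to the extent area.
    """
    if n_seeds < 3:
        raise ValueError("n_seeds must be >= 3")
    if not 0.0 <= sliver_fraction < 1.0:
        raise ValueError("sliver_fraction must lie in [0, 1)")
    xmin, ymin, xmax, ymax = extent
    rng = np.random.default_rng(rng_seed)
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, n_seeds), rng.uniform(ymin, ymax, n_seeds)]
    )
    # Mirror seeds across each extent edge so every interior region is finite.
    mirrors = [
        np.column_stack([2 * xmin - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * xmax - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymin - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymax - pts[:, 1]]),
    ]
    vor = Voronoi(np.vstack([pts] + mirrors))
    clip = box(xmin, ymin, xmax, ymax)
    cells: list[Polygon] = []
    for i in range(n_seeds):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(clip)
        if poly.is_empty or poly.area == 0:
            continue
        cells.append(poly)

    n_split = int(round(sliver_fraction * len(cells)))
    split_idx = set(rng.choice(len(cells), size=n_split, replace=False)) if n_split else set()
    zones: list[Zone] = []
    for i, cell in enumerate(cells):
        if i not in split_idx:
            zones.append(Zone(f"b{i}", cell))
            continue
        cx, cy = cell.centroid.x, cell.centroid.y
        angle = rng.uniform(0, math.pi)
        # Long thin rectangle through the centroid at a random angle.
        span = max(xmax - xmin, ymax - ymin)
        ux, uy = math.cos(angle), math.sin(angle)
        nx, ny = -uy * corridor_width / 2, ux * corridor_width / 2
        strip = Polygon(
            [
                (cx - ux * span + nx, cy - uy * span + ny),
                (cx + ux * span + nx, cy + uy * span + ny),
                (cx + ux * span - nx, cy + uy * span - ny),
                (cx - ux * span - nx, cy - uy * span - ny),
            ]
        )
        corridor = cell.intersection(strip)
        remainder = cell.difference(strip)
        if corridor.is_empty or remainder.is_empty:
            zones.append(Zone(f"b{i}", cell))
            continue
        zones.append(Zone(f"b{i}_road", corridor))
        parts = getattr(remainder, "geoms", [remainder])
        for k, part in enumerate(parts):
            if part.area > 0:
                zones.append(Zone(f"b{i}_{k}", part))
    return ZonePartition(PartitionKind.blocks, zones)


# ---------------------------------------------------------------------------
# Point-to-zone assignment (shared with geofence selection)


def assign_points(
    partition: ZonePartition, xs: Sequence[float], ys: Sequence[float]
) -> list[Optional[str]]:
    """Assign each point to the unique zone it falls in, or None.

    Boundary points follow the half-open rule: nudged by +epsilon in x and y,
    a point on a shared edge lands strictly inside the up-and-right zone.
    """
    polys = [z.polygon for z in partition.zones]
    tree = STRtree(polys)
    pts = shapely.points(np.asarray(xs, float) + _EPS, np.asarray(ys, float) + _EPS)
    out: list[Optional[str]] = [None] * len(pts)
    pt_i, poly_i = tree.query(pts, predicate="within")
    for p, z in zip(pt_i, poly_i):
        out[p] = partition.zones[z].zone_id
    return out


# ---------------------------------------------------------------------------
# Zonal statistics


def zonal_mean(
    raster: DensityRaster, partition: ZonePartition
) -> dict[str, Optional[float]]:
    """Arithmetic mean of raster values at the cell centers inside each zone.

    Zones containing no cell center (smaller or narrower than the raster
    cell) yield ``MISSING``; their count is logged, mirroring roadway blocks
    that fail to rasterize.
    """
    xs, ys = raster.cell_centers()
    cell = raster.cell_size
    means: dict[str, Optional[float]] = {}
    n_missing = 0
    for zone in partition.zones:
        bx0, by0, bx1, by1 = zone.polygon.bounds
        c0 = max(0, math.ceil((bx0 - _EPS - raster.x_origin) / cell - 0.5))
        c1 = min(raster.n_cols, math.floor((bx1 - raster.x_origin) / cell - 0.5) + 1)
        r0 = max(0, math.ceil((by0 - _EPS - raster.y_origin) / cell - 0.5))
        r1 = min(raster.n_rows, math.floor((by1 - raster.y_origin) / cell - 0.5) + 1)
        if c0 >= c1 or r0 >= r1:
            means[zone.zone_id] = MISSING
            n_missing += 1
            continue
        gx, gy = np.meshgrid(xs[c0:c1], ys[r0:r1])
        inside = shapely.contains_xy(zone.polygon, gx.ravel() + _EPS, gy.ravel() + _EPS)
        if not inside.any():
            means[zone.zone_id] = MISSING
            n_missing += 1
            continue
        means[zone.zone_id] = float(raster.values[r0:r1, c0:c1].ravel()[inside].mean())
    if n_missing:
        log.info(
            "%d of %d zones did not rasterize (no cell center inside) and are MISSING",
            n_missing,
            len(partition.zones),
        )
    return means


def normalize_minmax(
    means: Mapping[str, Optional[float]], decimals: int = 6
) -> dict[str, Optional[float]]:
    """Min-max rescale non-missing means to [0, 1], rounded to ``decimals``.

    If all non-missing means are equal the convention is norm = 1 for all of
    them (a single hotspot zone should be retained, not discarded). MISSING
    propagates. Rounding matters downstream: a raw norm of 0.9999984 rounds
    to 0.999998 at six decimals and is then excluded by a threshold of 1.0.
    """
    present = {z: m for z, m in means.items() if m is not MISSING}
    if not present:
        raise ValueError("all zone means are MISSING; nothing to normalize")
    lo, hi = min(present.values()), max(present.values())
    out: dict[str, Optional[float]] = {}
    for z, m in means.items():
        if m is MISSING:
            out[z] = MISSING
        elif hi == lo:
            out[z] = 1.0
        else:
            out[z] = round((m - lo) / (hi - lo), decimals)
    return out


def classify_terciles(
    norms: Mapping[str, Optional[float]],
    threshold: float,
    means: Mapping[str, Optional[float]] | None = None,
    partition_kind: PartitionKind | str = PartitionKind.custom,
) -> ZoneRiskTable:
    """Split retained zones (norm >= threshold, inclusive) into rank terciles.

    Retained zones are sorted ascending by norm and divided into three
    groups as equal in count as possible, remainders going to the lower
    groups (7 zones -> 3/2/2). Zones whose norm ties across a group boundary
    all drop to the lower group, so equal risk never straddles two labels.
    Zones below the threshold are ``not_retained``; zones without a norm are
    ``missing``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    retained = sorted(
        ((z, v) for z, v in norms.items() if v is not MISSING and v >= threshold),
        key=lambda t: (t[1], t[0]),
    )
    n = len(retained)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels: dict[str, Tercile] = {}
    groups: list[list[tuple[str, float]]] = []
    start = 0
    for size in sizes:
        groups.append(retained[start : start + size])
        start += size
    # Demote boundary ties into the lower group.
    for g in (1, 2):
        while groups[g] and groups[g - 1] and groups[g][0][1] == groups[g - 1][-1][1]:
            groups[g - 1].append(groups[g].pop(0))
    for group, terc in zip(groups, (Tercile.low, Tercile.medium, Tercile.high)):
        for z, _ in group:
            labels[z] = terc

    rows: dict[str, RiskRow] = {}
    for z, v in norms.items():
        if v is MISSING:
            terc = Tercile.missing
        else:
            terc = labels.get(z, Tercile.not_retained)
        mean = means.get(z) if means is not None else MISSING
        rows[z] = RiskRow(mean, v, terc)
    return ZoneRiskTable(PartitionKind(partition_kind), rows)


def build_risk_table(
    raster: DensityRaster,
    partition: ZonePartition,
    threshold: float,
    decimals: int = 6,
) -> ZoneRiskTable:
    """Convenience: zonal mean -> min-max normalize -> tercile classify."""
    means = zonal_mean(raster, partition)
    norms = normalize_minmax(means, decimals)
    return classify_terciles(norms, threshold, means, partition.partition_kind)
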