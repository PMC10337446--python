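"""Geofence scoring: capture rates, threshold sweeps, partition comparison.

The performance metric is the percent of a participant's (deduplicated)
smoking events falling inside the constructed geofences — in-sample, since
the same events built the fences. Field benchmarks: above 80% captured is
good, above 50% adequate.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import pandas as pd
import shapely
from shapely.geometry import MultiPolygon

from geofence_kde.core_io import ALL_BINS, PartitionKind, TimeBin, ZonePartition
from geofence_kde.geofence import (
    EMPTY,
    GeofenceSet,
    build_time_independent_fence,
)
from geofence_kde.preprocess import BinnedEvent, smoking_by_bin
from geofence_kde.zoning import ZoneRiskTable


def _covered(fence: MultiPolygon, events: Sequence[BinnedEvent]) -> int:
    """Events inside the fence, boundary inclusive (a device entering the
    perimeter should trigger)."""
    if fence.is_empty or not events:
        return 0
    pts = shapely.points([(b.event.x, b.event.y) for b in events])
    return int(shapely.covers(fence, pts).sum())


@dataclasses.dataclass(frozen=True)
class BinCapture:
    n_smoking: int
    n_captured: int

    @property
    def pct(self) -> Optional[float]:
        if self.n_smoking == 0:
            return None
        return round(100.0 * self.n_captured / self.n_smoking, 1)


@dataclasses.dataclass
class CaptureReport:
    """Per-bin and pooled capture statistics for one participant/partition."""

    participant_id: str
    partition_kind: PartitionKind
    threshold: float
    bins: dict[TimeBin, BinCapture]
    time_independent_pct: Optional[float]
    total_area_ft2: float

    @property
    def overall_n(self) -> int:
        return sum(b.n_smoking for b in self.bins.values())

    @property
    def overall_captured(self) -> int:
        return sum(b.n_captured for b in self.bins.values())

    @property
    def overall_pct(self) -> Optional[float]:
        n = self.overall_n
        return round(100.0 * self.overall_captured / n, 1) if n else None

    @property
    def mean_pct_unweighted(self) -> Optional[float]:
        """Unweighted mean over bins with at least one smoking event."""
        pcts = [b.pct for b in self.bins.values() if b.n_smoking > 0]
        return round(sum(pcts) / len(pcts), 1) if pcts else None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "bin": b.label,
                "n_smoking": c.n_smoking,
                "n_captured": c.n_captured,
                "pct_captured": c.pct,
            }
            for b, c in sorted(self.bins.items(), key=lambda t: t[0].index)
        ]
        rows.append(
            {
                "bin": "overall",
                "n_smoking": self.overall_n,
                "n_captured": self.overall_captured,
                "pct_captured": self.overall_pct,
            }
        )
        return pd.DataFrame(rows)


def capture_rate(
    fences: GeofenceSet,
    events: Sequence[BinnedEvent],
    time_independent_fence: MultiPolygon | None = None,
) -> CaptureReport:
    """Score per-bin geofences against the binned smoking events.

    An event is captured iff it falls inside (closure) its own bin's
    multipolygon. ``time_independent_fence``, when given, additionally scores
    all events pooled against the single fence built without time
    stratification.
    """
    participants = {b.event.participant_id for b in events}
    if len(participants) > 1:
        raise ValueError(f"events span multiple participants: {sorted(participants)}")
    if participants and fences.participant_id and {fences.participant_id} != participants:
        raise ValueError(
            f"fences are for {fences.participant_id!r} but events are for "
            f"{participants.pop()!r}"
        )
    by_bin = smoking_by_bin(events)
    bins = {
        b: BinCapture(len(evs), _covered(fences.fence(b), evs))
        for b, evs in by_bin.items()
    }
    ti_pct = None
    if time_independent_fence is not None:
        all_smoking = [e for evs in by_bin.values() for e in evs]
        if all_smoking:
            ti_pct = round(
                100.0 * _covered(time_independent_fence, all_smoking) / len(all_smoking), 1
            )
    return CaptureReport(
        fences.participant_id,
        fences.partition_kind,
        fences.threshold,
        bins,
        ti_pct,
        fences.total_area_ft2,
    )


def threshold_sweep(
    risk: ZoneRiskTable,
    partition: ZonePartition,
    events: Sequence[BinnedEvent],
    thresholds: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    buffer_m: float = 100.0,
    quad_segs: int = 32,
) -> pd.DataFrame:
    """Capture percent of time-independent geofences across thresholds.

    At each threshold, zones with norm >= threshold containing at least one
    smoking event (any time of day) are buffered into one fence and scored
    against all smoking events. Output rows are ordered by threshold with
    columns ``threshold, pct_captured, n_zones_retained, geofence_area_ft2``.
    """
    smoking = [
        e for evs in smoking_by_bin(events).values() for e in evs
    ]
    rows = []
    for t in sorted(thresholds):
        fence, ids = build_time_independent_fence(
            risk, partition, smoking, t, buffer_m, quad_segs
        )
        n = len(smoking)
        pct = round(100.0 * _covered(fence, smoking) / n, 1) if n else None
        rows.append(
            {
                "threshold": t,
                "pct_captured": pct,
                "n_zones_retained": len(ids),
                "geofence_area_ft2": fence.area,
            }
        )
    return pd.DataFrame(rows)


def case_summary(counts: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-case report composition, percentages to 1 decimal.

    ``counts`` maps a case label to (smoking, nonsmoking) event counts.
    ``pct_smoking``/``pct_nonsmoking`` are shares within the case's reports;
    ``pct_of_all_reports`` is the case's share of the pooled total.
    """
    grand_total = sum(s + n for s, n in counts.values())
    if grand_total == 0:
        raise ValueError("no reports at all")
    rows = []
    for case, (n_smoking, n_nonsmoking) in counts.items():
        total = n_smoking + n_nonsmoking
        rows.append(
            {
                "case": case,
                "n_smoking": n_smoking,
                "pct_smoking": round(100.0 * n_smoking / total, 1) if total else None,
                "n_nonsmoking": n_nonsmoking,
                "pct_nonsmoking": round(100.0 * n_nonsmoking / total, 1) if total else None,
                "n_total": total,
                "pct_of_all_reports": round(100.0 * total / grand_total, 1),
            }
        )
    return pd.DataFrame(rows)


def compare_partitions(reports: Sequence[CaptureReport]) -> pd.DataFrame:
    """Rank partitions by capture percent, per bin and overall.

    All reports must share the participant and threshold and differ in
    partition kind. Ranks are dense with ties shared (rank 1 = best). The
    total geofenced area is reported alongside: equal capture can come from
    very differently sized fences, which matters for alert burden.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    if len({r.participant_id for r in reports}) != 1:
        raise ValueError("reports must share a participant")
    if len({r.threshold for r in reports}) != 1:
        raise ValueError("reports must share a threshold")
    rows = []
    for r in reports:
        for b in ALL_BINS:
            c = r.bins.get(b)
            if c is None:
                continue
            rows.append(
                {
                    "scope": b.label,
                    "partition_kind": r.partition_kind.value,
                    "pct_captured": c.pct,
                    "total_area_ft2": r.total_area_ft2,
                }
            )
        rows.append(
            {
                "scope": "overall",
                "partition_kind": r.partition_kind.value,
                "pct_captured": r.overall_pct,
                "total_area_ft2": r.total_area_ft2,
            }
        )
    df = pd.DataFrame(rows)
    df["rank"] = (
        df.groupby("scope")["pct_captured"]
        .rank(method="dense", ascending=False)
        .astype("Int64")
    )
    df["tied"] = df.groupby(["scope", "pct_captured"], dropna=True)[
        "partition_kind"
    ].transform("count").gt(1)
    return df.sort_values(["scope", "rank"], na_position="last").reset_index(drop=True)
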