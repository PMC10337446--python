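"""Event-stream cleaning: duplicate-report removal and 3-hour time binning.

Smoking reports arriving within a few minutes of one another are treated as
double reports or app glitches and collapsed; nonsmoking reports are never
dropped. UTC timestamps are shifted by a fixed configured offset to local
time and assigned to one of eight half-open 3-hour bins [0,3), [3,6), ...
[21,24).
"""

from __future__ import annotations

import dataclasses
from datetime import datetime, timedelta
from typing import Iterable, Sequence

from geofence_kde.core_io import ConfigError, EmaEvent, EventKind, TimeBin


@dataclasses.dataclass(frozen=True)
class BinnedEvent:
    """An event annotated with its local timestamp and 3-hour bin."""

    event: EmaEvent
    local_timestamp: datetime
    bin: TimeBin


def dedupe_smoking(
    events: Iterable[EmaEvent],
    window_min: float = 5.0,
    keep: str = "first",
) -> tuple[list[EmaEvent], int]:
    """Drop smoking reports closer than ``window_min`` minutes to the last
    retained smoking report.

    The rule is greedy in chronological order: a smoking event survives iff
    it is at least ``window_min`` minutes after the most recently *retained*
    smoking event, so a burst of reports 3 minutes apart collapses to roughly
    one per window rather than to a single report. Nonsmoking events pass
    through untouched. ``keep="last"`` reverses time before applying the rule
    (so the latest report of each burst survives) and is exposed for
    sensitivity checks.

    Returns ``(retained_events, n_dropped)``. Retained events are sorted
    ascending by timestamp; timestamp ties keep input order.
    """
    if window_min <= 0:
        raise ConfigError("dedup window must be positive")
    if keep not in ("first", "last"):
        raise ConfigError("keep must be 'first' or 'last'")
    ordered = sorted(enumerate(events), key=lambda t: (t[1].timestamp_utc, t[0]))
    participants = {e.participant_id for _, e in ordered}
    if len(participants) > 1:
        raise ConfigError(f"events span multiple participants: {sorted(participants)}")
    if keep == "last":
        ordered = ordered[::-1]
    window = timedelta(minutes=window_min)
    retained: list[EmaEvent] = []
    last_kept: datetime | None = None
    dropped = 0
    for _, e in ordered:
        if e.kind is EventKind.smoking:
            if last_kept is not None and abs(e.timestamp_utc - last_kept) < window:
                dropped += 1
                continue
            last_kept = e.timestamp_utc
        retained.append(e)
    retained.sort(key=lambda e: e.timestamp_utc)
    return retained, dropped


def assign_bins(
    events: Sequence[EmaEvent], utc_offset_hours: float
) -> list[BinnedEvent]:
    """Convert to local time by a fixed offset and assign 3-hour bins.

    Every event lands in exactly one bin; boundaries are half-open, so a
    local 03:00:00 report belongs to the 3-6 bin, not the midnight bin.
    """
    offset = timedelta(hours=utc_offset_hours)
    out = []
    for e in events:
        local = e.timestamp_utc + offset
        out.append(BinnedEvent(e, local, TimeBin.for_hour(local.hour)))
    return out


def smoking_by_bin(binned: Iterable[BinnedEvent]) -> dict[TimeBin, list[BinnedEvent]]:
    """Group the smoking events of a binned stream by time bin."""
    groups: dict[TimeBin, list[BinnedEvent]] = {TimeBin(i): [] for i in range(8)}
    for b in binned:
        if b.event.kind is EventKind.smoking:
            groups[b.bin].append(b)
    return groups
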