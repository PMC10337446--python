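"""Synthetic EMA participants with the spatial structure the method assumes.

The study's raw GPS traces are not deposited, so testing needs generated
streams with the same statistical shape: 30 days of smoking and nonsmoking
self-reports, smoking spatially clustered around a handful of anchor
locations (home, workplace, a bar) with time-of-day profiles, plus one
"dispersed" regime where a minority of events concentrate in two zones and
the rest scatter across the map — the regime in which zone-based geofences
underperform.

The generator is an anchors-and-background mixture: each event draws a
3-hour bin from a diurnal profile, an anchor according to that bin's anchor
weights, and a location from the anchor's isotropic Gaussian scatter — or,
with probability ``dispersion``, uniformly over the extent. Events are the
only observable the pipeline consumes; no mobility trajectory is simulated.
All randomness flows through one seeded generator per participant.
"""

from __future__ import annotations

import dataclasses
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np

from geofence_kde.core_io import EmaEvent, EventKind, ZonePartition
from geofence_kde.zoning import make_fishnet, make_pseudo_blocks

#: Reports start at local midnight of this (arbitrary) study day 1.
STUDY_START_UTC = datetime(2026, 3, 2, 8, 0, 0, tzinfo=timezone.utc)  # local 00:00 at UTC-8

#: At most this many nonsmoking (random prompt) surveys per day.
MAX_NONSMOKING_PER_DAY = 3


@dataclasses.dataclass(frozen=True)
class Anchor:
    """A habitual smoking location with per-bin usage weights.

    ``bin_weights`` has 8 entries; across a profile's anchors the weights of
    each bin sum to 1 (given that an event happens in that bin at an anchor,
    they say at which one).
    """

    x: float
    y: float
    scatter_sd: float  # ft, isotropic Gaussian
    bin_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.bin_weights) != 8:
            raise ValueError("bin_weights must have 8 entries")
        if self.scatter_sd < 0:
            raise ValueError("scatter_sd must be non-negative")


@dataclasses.dataclass
class ParticipantProfile:
    """Generator settings for one synthetic participant.

    ``bin_probs`` is the diurnal profile (probability an event falls in each
    3-hour bin); ``dispersion`` is the probability an event location is
    uniform over ``extent`` instead of anchored; ``duplicate_rate`` injects
    double smoking reports under 5 minutes apart to exercise deduplication.
    """

    participant_id: str
    anchors: Sequence[Anchor]
    smoking_events_per_day: float
    nonsmoking_surveys_per_day: float
    bin_probs: tuple[float, ...] = (0.02, 0.01, 0.07, 0.15, 0.20, 0.20, 0.20, 0.15)
    dispersion: float = 0.0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 20000.0, 20000.0)
    n_days: int = 30
    duplicate_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.smoking_events_per_day < 0 or self.nonsmoking_surveys_per_day < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.dispersion <= 1.0:
            raise ValueError("dispersion must lie in [0, 1]")
        if len(self.bin_probs) != 8 or abs(sum(self.bin_probs) - 1.0) > 1e-9:
            raise ValueError("bin_probs must be 8 probabilities summing to 1")
        for b in range(8):
            total = sum(a.bin_weights[b] for a in self.anchors)
            if self.anchors and abs(total - 1.0) > 1e-9:
                raise ValueError(f"anchor weights for bin {b} sum to {total}, not 1")


def _clip_to_extent(x: float, y: float, extent) -> tuple[float, float]:
    xmin, ymin, xmax, ymax = extent
    return min(max(x, xmin), xmax), min(max(y, ymin), ymax)


def _draw_location(
    profile: ParticipantProfile, bin_index: int, rng: np.random.Generator
) -> tuple[float, float]:
    xmin, ymin, xmax, ymax = profile.extent
    if not profile.anchors or rng.random() < profile.dispersion:
        return rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)
    weights = np.array([a.bin_weights[bin_index] for a in profile.anchors])
    anchor = profile.anchors[rng.choice(len(profile.anchors), p=weights)]
    x = anchor.x + rng.normal(0, anchor.scatter_sd)
    y = anchor.y + rng.normal(0, anchor.scatter_sd)
    return _clip_to_extent(x, y, profile.extent)


def gen_participant(profile: ParticipantProfile) -> list[EmaEvent]:
    """Generate one participant's 30-day event stream, sorted by time.

    Daily smoking counts are Poisson at the profile rate; nonsmoking survey
    counts are Poisson capped at 3 per day. Each event samples a 3-hour bin
    from the diurnal profile, a uniform second within the bin, and a
    location from the anchors-and-background mixture. With probability
    ``duplicate_rate`` a smoking event spawns a near-duplicate report less
    than 5 minutes later at nearly the same spot.
    """
    rng = np.random.default_rng(profile.rng_seed)
    events: list[EmaEvent] = []
    for day in range(profile.n_days):
        day_start = STUDY_START_UTC + timedelta(days=day)
        n_smoking = rng.poisson(profile.smoking_events_per_day)
        n_nonsmoking = min(
            rng.poisson(profile.nonsmoking_surveys_per_day), MAX_NONSMOKING_PER_DAY
        )
        for kind, count in ((EventKind.smoking, n_smoking), (EventKind.nonsmoking, n_nonsmoking)):
            for _ in range(count):
                b = int(rng.choice(8, p=profile.bin_probs))
                seconds = int(rng.uniform(0, 3 * 3600))  # whole seconds, like an EMA app
                ts = day_start + timedelta(hours=3 * b, seconds=seconds)
                x, y = _draw_location(profile, b, rng)
                events.append(EmaEvent(profile.participant_id, ts, x, y, kind))
                if kind is EventKind.smoking and rng.random() < profile.duplicate_rate:
                    dup_ts = ts + timedelta(seconds=int(rng.uniform(30, 270)))
                    jx, jy = _clip_to_extent(
                        x + rng.normal(0, 10), y + rng.normal(0, 10), profile.extent
                    )
                    events.append(
                        EmaEvent(profile.participant_id, dup_ts, jx, jy, EventKind.smoking)
                    )
    events.sort(key=lambda e: e.timestamp_utc)
    return events


# ---------------------------------------------------------------------------
# The four-case suite

#: Per-case (smoking total, nonsmoking total) the generator is calibrated to.
#: Compliance quartiles of the emulated study: smoking totals span 12-177,
#: nonsmoking 8-67. Rates are totals / 30 days; the heaviest case's rate is
#: backed off slightly so its realized Poisson total stays within the range.
CASE_TARGETS = {
    "q25": (16, 8),
    "q50": (12, 47),
    "q75": (31, 67),
    "q100": (168, 61),
}

SMOKING_RANGE = (12, 177)
NONSMOKING_RANGE = (8, 67)


@dataclasses.dataclass
class CaseSuite:
    """Four synthetic participants plus the three shared zone partitions."""

    profiles: dict[str, ParticipantProfile]
    events: dict[str, list[EmaEvent]]
    blocks: ZonePartition
    fishnet_500: ZonePartition
    fishnet_1000: ZonePartition

    @property
    def partitions(self) -> dict[str, ZonePartition]:
        return {
            "blocks": self.blocks,
            "fishnet_500": self.fishnet_500,
            "fishnet_1000": self.fishnet_1000,
        }


def _case_profile(case: str, seed: int, extent) -> ParticipantProfile:
    smoking_total, nonsmoking_total = CASE_TARGETS[case]
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = extent
    # Anchors sit well inside the extent so their scatter stays on-map.
    pad = 0.2 * (xmax - xmin)
    n_anchors = 3 if case != "q100" else 2
    ax = rng.uniform(xmin + pad, xmax - pad, n_anchors)
    ay = rng.uniform(ymin + pad, ymax - pad, n_anchors)
    # Usage weights: one dominant "home" anchor at night, spread by day.
    weights = np.zeros((n_anchors, 8))
    for b in range(8):
        w = rng.dirichlet(np.full(n_anchors, 0.8))
        if b in (0, 7):  # night bins lean on the first anchor
            w = 0.3 * w + 0.7 * np.eye(n_anchors)[0]
        weights[:, b] = w / w.sum()
    anchors = [
        Anchor(float(ax[i]), float(ay[i]), scatter_sd=200.0, bin_weights=tuple(weights[i]))
        for i in range(n_anchors)
    ]
    return ParticipantProfile(
        participant_id=case,
        anchors=anchors,
        smoking_events_per_day=smoking_total / 30.0,
        nonsmoking_surveys_per_day=nonsmoking_total / 30.0,
        dispersion=0.55 if case == "q100" else 0.03,
        extent=extent,
        duplicate_rate=0.05,
        rng_seed=seed,
    )


def gen_case_suite(seed: int, extent=(0.0, 0.0, 20000.0, 20000.0)) -> CaseSuite:
    """Generate the four-case study: 4 participants, 3 shared partitions.

    Three cases are anchor-concentrated; the heaviest-reporting case is
    spatially dispersed (over half its events scattered off-anchor). Each
    case's stream is redrawn with a derived seed until its realized totals
    fall within the calibrated ranges (smoking 12-177, nonsmoking 8-67,
    counting smoking after the 5-minute duplicate-report rule, since that is
    the count any analysis sees); a handful of redraws at most. Partitions
    cover the full extent, so every generated event lies inside them.
    """
    from geofence_kde.preprocess import dedupe_smoking

    profiles: dict[str, ParticipantProfile] = {}
    events: dict[str, list[EmaEvent]] = {}
    for i, case in enumerate(CASE_TARGETS):
        for attempt in range(50):
            sub_seed = (seed * 7919 + i * 1009 + attempt * 101) % (2**31)
            profile = _case_profile(case, sub_seed, extent)
            stream = gen_participant(profile)
            clean, _ = dedupe_smoking(stream)
            n_smoking = sum(1 for e in clean if e.kind is EventKind.smoking)
            n_nonsmoking = sum(1 for e in clean if e.kind is EventKind.nonsmoking)
            if (
                SMOKING_RANGE[0] <= n_smoking <= SMOKING_RANGE[1]
                and NONSMOKING_RANGE[0] <= n_nonsmoking <= NONSMOKING_RANGE[1]
            ):
                profiles[case] = profile
                events[case] = stream
                break
        else:  # pragma: no cover - calibration leaves wide margins
            raise RuntimeError(f"case {case}: could not realize calibrated totals")
    blocks = make_pseudo_blocks(
        extent, n_seeds=120, rng_seed=seed % (2**31), sliver_fraction=0.15
    )
    return CaseSuite(
        profiles,
        events,
        blocks=blocks,
        fishnet_500=make_fishnet(extent, 500.0),
        fishnet_1000=make_fishnet(extent, 1000.0),
    )
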