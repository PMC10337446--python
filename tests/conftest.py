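"""Shared fixtures: event builders and a raster-aligned mini study area.

The "aligned" fixtures place two sentinel smoking events so that the event
bounding box padded by the bandwidth covers the partition extent exactly;
every fishnet cell then contains raster cell centers, which isolates the
sliver-rasterization failure mode to the irregular block partitions.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from geofence_kde.core_io import EmaEvent, EventKind
from geofence_kde.kde import KdeParams, kde_surface, make_grid
from geofence_kde.preprocess import assign_bins

T0 = datetime(2026, 3, 2, 8, 0, 0, tzinfo=timezone.utc)  # local midnight at UTC-8


def event(
    x: float,
    y: float,
    minutes: float = 0.0,
    kind: EventKind = EventKind.smoking,
    participant: str = "p1",
) -> EmaEvent:
    return EmaEvent(participant, T0 + timedelta(minutes=minutes), x, y, kind)


@pytest.fixture
def make_events():
    return event


#: Extent whose corners minus the bandwidth padding are reachable by the
#: sentinel events below: raster covers [0, 6000]^2 exactly.
ALIGNED_EXTENT = (0.0, 0.0, 6000.0, 6000.0)
TAU = 1320.0


def aligned_events(cluster_xy=(3000.0, 3000.0), n_cluster=12, spread=120.0):
    """A tight smoking cluster plus two sentinel events pinning the raster
    to cover ALIGNED_EXTENT. Deterministic, no randomness."""
    cx, cy = cluster_xy
    evs = [event(TAU, TAU, minutes=0.0), event(6000.0 - TAU, 6000.0 - TAU, minutes=30.0)]
    for i in range(n_cluster):
        dx = spread * ((i % 5) - 2) / 2.0
        dy = spread * ((i // 5) - 1) / 2.0
        evs.append(event(cx + dx, cy + dy, minutes=60.0 + 10 * i))
    return evs


@pytest.fixture
def aligned_raster():
    evs = aligned_events()
    params = KdeParams(TAU, 150.0)
    raster = kde_surface(evs, make_grid(evs, params), params)
    assert (raster.x_origin, raster.y_origin) == (0.0, 0.0)
    assert (raster.n_cols, raster.n_rows) == (40, 40)
    return raster


@pytest.fixture
def aligned_binned():
    return assign_bins(aligned_events(), utc_offset_hours=-8.0)


@pytest.fixture(scope="session")
def case_suite():
    """One shared synthetic four-case study for the heavier tests."""
    from geofence_kde.synthgen import gen_case_suite

    return gen_case_suite(seed=7)
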