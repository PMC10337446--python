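"""Participant-specific kernel density surface of smoking events.

The density at a grid point g is a sum of compact-support kernel weights
over events i within the bandwidth tau:

    f(g) = sum_{d_ig < tau}  (3 / (pi tau^2)) * (1 - d_ig^2 / tau^2)^2

with d_ig the planar Euclidean distance. This is the quartic (biweight)
kernel used by the standard GIS kernel-density tools; its weight is exactly
zero at distance tau, so each event influences only a disc of radius tau.
Units are events per square foot; a downstream min-max normalization makes
the absolute scale irrelevant, but the raster writer records it.

The evaluation grid covers the event bounding box padded by tau on all
sides (so the surface decays to zero inside the raster) and is evaluated at
square-cell centers.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from geofence_kde.core_io import EmaEvent

NODATA = -9999.0


@dataclasses.dataclass(frozen=True)
class KdeParams:
    """Kernel parameters: bandwidth tau and output cell side, both US feet."""

    bandwidth_tau: float = 1320.0
    cell_size: float = 150.0
    kernel: str = "quartic"

    def __post_init__(self) -> None:
        if self.bandwidth_tau <= 0:
            raise ValueError("bandwidth_tau must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.kernel != "quartic":
            raise ValueError(f"unsupported kernel {self.kernel!r}")


@dataclasses.dataclass
class DensityRaster:
    """A regular grid of density values.

    ``values[r, c]`` is the density at the center of the cell in row r
    (row 0 is the SOUTHERNMOST row, matching the lower-left origin) and
    column c. The center of cell (r, c) is at
    ``(x_origin + (c + 0.5) * cell_size, y_origin + (r + 0.5) * cell_size)``.
    """

    x_origin: float
    y_origin: float
    cell_size: float
    values: np.ndarray  # (n_rows, n_cols), float64

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as broadcastable (xs of cols, ys of rows)."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_origin + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def write_ascii(self, path: str | Path) -> None:
        """Write as an Esri ASCII grid (units: events per square foot)."""
        with open(path, "w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {self.x_origin!r}\n")
            fh.write(f"yllcorner {self.y_origin!r}\n")
            fh.write(f"cellsize {self.cell_size!r}\n")
            fh.write(f"NODATA_value {NODATA}\n")
            # ASCII grids store the top row first
            for row in self.values[::-1]:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "DensityRaster":
        with open(path) as fh:
            header: dict[str, float] = {}
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)[::-1].copy()
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("ASCII grid shape does not match its header")
        return cls(header["xllcorner"], header["yllcorner"], header["cellsize"], values)


def make_grid(events: Sequence[EmaEvent], params: KdeParams) -> DensityRaster:
    """Frame an all-zero raster covering the events padded by tau.

    The origin is the event bounding box minus tau, snapped down to a
    multiple of the cell size (so grids of shifted-but-snapped event sets
    align); the extent covers the box plus tau.
    """
    if not events:
        raise ValueError("no events: skip this participant")
    xs = [e.x for e in events]
    ys = [e.y for e in events]
    tau, cell = params.bandwidth_tau, params.cell_size
    x0 = math.floor((min(xs) - tau) / cell) * cell
    y0 = math.floor((min(ys) - tau) / cell) * cell
    n_cols = math.ceil((max(xs) + tau - x0) / cell)
    n_rows = math.ceil((max(ys) + tau - y0) / cell)
    return DensityRaster(x0, y0, cell, np.zeros((n_rows, n_cols)))


def kde_surface(
    events: Sequence[EmaEvent], grid: DensityRaster, params: KdeParams
) -> DensityRaster:
    """Evaluate the quartic-kernel density of ``events`` on ``grid``.

    Complexity is O(events x cells-within-tau): each event touches only the
    raster window its tau-disc intersects, which at the study scale (a few
    hundred events) needs no spatial index.
    """
    tau = params.bandwidth_tau
    norm = 3.0 / (math.pi * tau * tau)
    values = np.zeros_like(grid.values)
    xs, ys = grid.cell_centers()
    cell = grid.cell_size
    for e in events:
        c0 = max(0, int((e.x - tau - grid.x_origin) / cell) - 1)
        c1 = min(grid.n_cols, int((e.x + tau - grid.x_origin) / cell) + 2)
        r0 = max(0, int((e.y - tau - grid.y_origin) / cell) - 1)
        r1 = min(grid.n_rows, int((e.y + tau - grid.y_origin) / cell) + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = xs[c0:c1] - e.x
        dy = ys[r0:r1] - e.y
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        u = 1.0 - d2 / (tau * tau)
        np.maximum(u, 0.0, out=u)
        values[r0:r1, c0:c1] += norm * u * u
    return DensityRaster(grid.x_origin, grid.y_origin, grid.cell_size, values)
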