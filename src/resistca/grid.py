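"""Spatial lattice and monthly time axis.

The model operates on a regular grid of square cells on a single projected
plane (kilometre coordinates; default cell size 5 km) and a monthly time
axis. Cell ``(i, j)`` covers the half-open square

    [origin_x + j*s, origin_x + (j+1)*s) x [origin_y + i*s, origin_y + (i+1)*s)

so every in-bounds point belongs to exactly one cell and the row index
increases with y. Driver data supplied on a yearly basis are expanded to
monthly steps here: yearly values are anchored at January of their year,
months between anchors are linearly interpolated, and months outside the
anchored range are held constant at the nearest anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import OutOfDomainError

__all__ = [
    "GridSpec",
    "TimeAxis",
    "build_grid",
    "point_to_cell",
    "centroids",
    "interpolate_to_monthly",
    "nearest_anchor_monthly",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular lattice of square cells on a planar km coordinate system."""

    origin_x: float
    origin_y: float
    n_rows: int
    n_cols: int
    cell_size: float = 5.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    def contains(self, x: float, y: float) -> bool:
        return (
            self.origin_x <= x < self.origin_x + self.width
            and self.origin_y <= y < self.origin_y + self.height
        )

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size": self.cell_size,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(
            origin_x=float(d["origin_x"]),
            origin_y=float(d["origin_y"]),
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            cell_size=float(d.get("cell_size", 5.0)),
        )


@dataclass(frozen=True)
class TimeAxis:
    """Consecutive calendar months starting at (start_year, start_month)."""

    start_year: int
    start_month: int
    n_steps: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_month <= 12:
            raise ValueError(f"start_month must be in 1..12, got {self.start_month}")
        if self.n_steps < 1:
            raise ValueError("time axis needs at least one step")

    def month_at(self, step: int) -> tuple[int, int]:
        """Calendar (year, month) of step index ``step`` (0-based)."""
        if not 0 <= step < self.n_steps:
            raise IndexError(f"step {step} outside axis of length {self.n_steps}")
        m = (self.start_year * 12 + self.start_month - 1) + step
        return divmod(m, 12)[0], divmod(m, 12)[1] + 1

    def index_of(self, year: int, month: int) -> int:
        k = (year * 12 + month - 1) - (self.start_year * 12 + self.start_month - 1)
        if not 0 <= k < self.n_steps:
            raise IndexError(f"{year}-{month:02d} outside time axis")
        return k

    def steps_in_year(self, year: int) -> list[int]:
        return [k for k in range(self.n_steps) if self.month_at(k)[0] == year]

    def years(self) -> list[int]:
        return sorted({self.month_at(k)[0] for k in range(self.n_steps)})

    def to_dict(self) -> dict:
        return {
            "start_year": self.start_year,
            "start_month": self.start_month,
            "n_steps": self.n_steps,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TimeAxis":
        return cls(int(d["start_year"]), int(d["start_month"]), int(d["n_steps"]))

    def _abs_months(self) -> np.ndarray:
        start = self.start_year * 12 + self.start_month - 1
        return np.arange(start, start + self.n_steps)


def build_grid(
    origin_x: float,
    origin_y: float,
    width: float,
    height: float,
    cell_size: float = 5.0,
) -> GridSpec:
    """Cover a ``width`` x ``height`` km extent with square cells.

    The cell count rounds up, so the grid may overhang the requested extent
    by less than one cell on the right/top.
    """
    if width <= 0 or height <= 0 or cell_size <= 0:
        raise ValueError("width, height and cell_size must all be positive")
    return GridSpec(
        origin_x=origin_x,
        origin_y=origin_y,
        n_rows=ceil(height / cell_size),
        n_cols=ceil(width / cell_size),
        cell_size=cell_size,
    )


def point_to_cell(x: float, y: float, grid: GridSpec) -> tuple[int, int]:
    """Map a planar point to the unique cell whose half-open square holds it."""
    if not grid.contains(x, y):
        raise OutOfDomainError(f"point ({x}, {y}) outside grid bounds")
    j = floor((x - grid.origin_x) / grid.cell_size)
    i = floor((y - grid.origin_y) / grid.cell_size)
    # guard against float round-off at the extreme upper edge
    return min(i, grid.n_rows - 1), min(j, grid.n_cols - 1)


def centroids(grid: GridSpec) -> pd.DataFrame:
    """Cell centres, one row per cell, columns i, j, x_center, y_center."""
    ii, jj = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    return pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "x_center": grid.origin_x + (jj.ravel() + 0.5) * grid.cell_size,
            "y_center": grid.origin_y + (ii.ravel() + 0.5) * grid.cell_size,
        }
    )


def _anchor_months_values(yearly_values: Mapping[int, float]) -> tuple[np.ndarray, np.ndarray]:
    if not yearly_values:
        raise ValueError("at least one yearly anchor is required")
    years = np.array(sorted(yearly_values), dtype=int)
    vals = np.array([float(yearly_values[y]) for y in years])
    return years * 12, vals  # January of each year, as absolute month numbers


def interpolate_to_monthly(
    yearly_values: Mapping[int, float], axis: TimeAxis
) -> np.ndarray:
    """Expand yearly values to the monthly axis.

    Each yearly value anchors at January of its year; months between anchors
    are linearly interpolated and months outside the anchor range are held
    constant at the nearest anchor. Anchored months reproduce their yearly
    value exactly.
    """
    anchors, vals = _anchor_months_values(yearly_values)
    return np.interp(axis._abs_months(), anchors, vals)


def nearest_anchor_monthly(
    yearly_values: Mapping[int, float], axis: TimeAxis
) -> np.ndarray:
    """Step-function expansion for categorical series: nearest anchor's value.

    Ties (exactly between two anchors) resolve to the earlier anchor.
    """
    anchors, vals = _anchor_months_values(yearly_values)
    dist = np.abs(axis._abs_months()[:, None] - anchors[None, :])
    return vals[np.argmin(dist, axis=1)]
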