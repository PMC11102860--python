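"""Readers and writers for records, driver layers, state rasters and rules.

Formats are deliberately plain: susceptibility-test records travel as CSV
with columns ``x,y,date,species,insecticide_class,mortality_pct`` (extra
columns ignored), driver and state rasters as either multi-band TIFF (one
band per time step) or a gridded CSV with ``i,j,t,value`` / ``i,j,year,value``
columns, and rule sets as JSON. Coordinates are planar kilometres on the
model grid; real lon/lat data must be pre-projected upstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError
from .grid import GridSpec, TimeAxis, interpolate_to_monthly, nearest_anchor_monthly
from .rules import RuleSet

__all__ = [
    "INSECTICIDE_CLASSES",
    "SusceptibilityRecord",
    "RecordReadResult",
    "DriverLayer",
    "DriverStack",
    "read_records",
    "write_records",
    "read_driver_layer",
    "write_driver_layer_csv",
    "write_state_raster",
    "read_state_raster",
    "read_ruleset",
    "write_ruleset",
]

logger = logging.getLogger(__name__)

INSECTICIDE_CLASSES = ("pyrethroid", "organochlorine", "carbamate", "organophosphate")

_RECORD_COLUMNS = ("x", "y", "date", "species", "insecticide_class", "mortality_pct")


@dataclass(frozen=True)
class SusceptibilityRecord:
    """One georeferenced bioassay result: % mortality after insecticide exposure."""

    x: float
    y: float
    year: int
    month: int
    species: str
    insecticide_class: str
    mortality_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mortality_pct <= 100.0:
            raise ValueError(f"mortality_pct {self.mortality_pct} outside [0, 100]")
        if self.insecticide_class not in INSECTICIDE_CLASSES:
            raise ValueError(f"unknown insecticide class {self.insecticide_class!r}")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month {self.month} outside 1..12")

    @property
    def date(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


@dataclass
class RecordReadResult:
    """Parsed records plus counts of rows dropped or rejected on the way in."""

    records: list[SusceptibilityRecord]
    n_dropped_coords: int = 0
    n_rejected_invalid: int = 0

    def __iter__(self) -> Iterator[SusceptibilityRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_records(path) -> RecordReadResult:
    """Read susceptibility records from CSV.

    Rows with missing or unparseable coordinates are dropped and counted
    separately from rows rejected for violating record invariants (mortality
    outside [0, 100], unknown insecticide class, unparseable date).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"records file {path} missing columns {missing}")

    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    keep = x.notna() & y.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d non-georeferenced rows from %s", n_dropped, path)

    records: list[SusceptibilityRecord] = []
    n_rejected = 0
    dates = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    mort = pd.to_numeric(df["mortality_pct"], errors="coerce")
    for idx in df.index[keep]:
        d = dates[idx]
        m = mort[idx]
        if pd.isna(d) or pd.isna(m):
            n_rejected += 1
            continue
        try:
            records.append(
                SusceptibilityRecord(
                    x=float(x[idx]),
                    y=float(y[idx]),
                    year=int(d.year),
                    month=int(d.month),
                    species=str(df["species"][idx]),
                    insecticide_class=str(df["insecticide_class"][idx]),
                    mortality_pct=float(m),
                )
            )
        except ValueError as exc:
            logger.warning("rejected row %d: %s", idx, exc)
            n_rejected += 1
    return RecordReadResult(records, n_dropped, n_rejected)


def write_records(records: Sequence[SusceptibilityRecord], path) -> None:
    pd.DataFrame(
        {
            "x": [r.x for r in records],
            "y": [r.y for r in records],
            "date": [r.date for r in records],
            "species": [r.species for r in records],
            "insecticide_class": [r.insecticide_class for r in records],
            "mortality_pct": [r.mortality_pct for r in records],
        }
    ).to_csv(path, index=False)


@dataclass
class DriverLayer:
    """One gridded driver aligned to a grid and monthly axis."""

    name: str
    kind: str  # 'continuous' | 'categorical'
    values: np.ndarray  # (n_steps, n_rows, n_cols)
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"kind must be continuous or categorical, got {self.kind!r}")


@dataclass
class DriverStack:
    """Named driver layers stacked on one grid and one monthly time axis."""

    grid: GridSpec
    axis: TimeAxis
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)
    legends: dict[str, dict[int, str]] = field(default_factory=dict)

    def add(self, layer: DriverLayer) -> "DriverStack":
        expected = (self.axis.n_steps, self.grid.n_rows, self.grid.n_cols)
        if layer.values.shape != expected:
            raise FormatError(
                f"layer {layer.name!r} shape {layer.values.shape} != {expected}"
            )
        self.layers[layer.name] = layer.values
        self.kinds[layer.name] = layer.kind
        if layer.legend:
            self.legends[layer.name] = dict(layer.legend)
        return self

    def at(self, step: int) -> dict[str, np.ndarray]:
        """Per-cell driver values at one time step (views, do not mutate)."""
        return {name: arr[step] for name, arr in self.layers.items()}

    def names(self) -> list[str]:
        return list(self.layers)


def _expand_yearly(
    bands: np.ndarray, years: Sequence[int], axis: TimeAxis, kind: str
) -> np.ndarray:
    """Expand (n_years, r, c) yearly bands to (n_steps, r, c) monthly slices."""
    order = np.argsort(years)
    years_sorted = [int(years[k]) for k in order]
    bands = bands[order]
    nb, r, c = bands.shape
    flat = bands.reshape(nb, r * c)
    out = np.empty((axis.n_steps, r * c), dtype=float)
    if kind == "categorical":
        for col in range(r * c):
            out[:, col] = nearest_anchor_monthly(
                dict(zip(years_sorted, flat[:, col])), axis
            )
    else:
        for col in range(r * c):
            out[:, col] = interpolate_to_monthly(
                dict(zip(years_sorted, flat[:, col])), axis
            )
    return out.reshape(axis.n_steps, r, c)


def read_driver_layer(
    path,
    grid: GridSpec,
    axis: TimeAxis,
    name: str,
    kind: str = "continuous",
    years: Sequence[int] | None = None,
    legend: Mapping[int, str] | None = None,
) -> DriverLayer:
    """Read one driver layer from multi-band TIFF or gridded CSV.

    With ``years`` given, bands are yearly anchors: continuous layers are
    linearly interpolated to the monthly axis and categorical layers stepped
    to the nearest anchor (codes are never interpolated). Without ``years``
    the band count must equal the axis length.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(path), dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        tcol = "t" if "t" in df.columns else "year" if "year" in df.columns else None
        if tcol is None or not {"i", "j", "value"} <= set(df.columns):
            raise FormatError(f"gridded CSV {path} needs columns i,j,{{t|year}},value")
        tvals = sorted(df[tcol].unique())
        if tcol == "year" and years is None:
            years = [int(t) for t in tvals]
        arr = np.full((len(tvals), grid.n_rows, grid.n_cols), np.nan)
        pos = {t: k for k, t in enumerate(tvals)}
        for _, row in df.iterrows():
            arr[pos[row[tcol]], int(row["i"]), int(row["j"])] = row["value"]

    if arr.shape[1:] != (grid.n_rows, grid.n_cols):
        raise FormatError(
            f"raster {path} shape {arr.shape[1:]} does not match grid {grid.shape}"
        )
    if years is not None:
        if len(years) != arr.shape[0]:
            raise FormatError(
                f"{len(years)} years given for {arr.shape[0]} bands in {path}"
            )
        arr = _expand_yearly(arr, list(years), axis, kind)
    elif arr.shape[0] != axis.n_steps:
        raise FormatError(
            f"raster {path} has {arr.shape[0]} bands for a {axis.n_steps}-step axis "
            "and no 'years' mapping"
        )
    return DriverLayer(name=name, kind=kind, values=arr, legend=dict(legend or {}))


def write_driver_layer_csv(layer: DriverLayer, path) -> None:
    """Write a layer as gridded CSV with i,j,t,value columns."""
    t, i, j = np.indices(layer.values.shape)
    pd.DataFrame(
        {
            "i": i.ravel(),
            "j": j.ravel(),
            "t": t.ravel(),
            "value": layer.values.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip


def write_state_raster(states: Sequence, path) -> None:
    """Write a state sequence as multi-band TIFF, one {0,1} band per step."""
    arrs = [np.asarray(getattr(s, "values", s), dtype=np.uint8) for s in states]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"state grids have mixed shapes {shapes}")
    tifffile.imwrite(path, np.stack(arrs))


def read_state_raster(path) -> np.ndarray:
    """Read a state raster back as a (n_steps, n_rows, n_cols) {0,1} array."""
    arr = np.asarray(tifffile.imread(path), dtype=np.uint8)
    if arr.ndim == 2:
        arr = arr[None]
    bad = set(np.unique(arr)) - {0, 1}
    if bad:
        raise FormatError(f"state raster {path} holds non-binary values {sorted(bad)}")
    return arr


def read_ruleset(path) -> RuleSet:
    """Read a rule-set JSON document; schema errors name the offending clause."""
    with open(path) as fh:
        doc = json.load(fh)
    return RuleSet.from_dict(doc)


def write_ruleset(ruleset: RuleSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(ruleset.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
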