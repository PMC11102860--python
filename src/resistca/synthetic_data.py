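"""Seeded synthetic driver fields, ground-truth dynamics and bioassay records.

Real inputs to the model — gridded environmental/agricultural/intervention
driver layers and georeferenced susceptibility-test records — require large
external databases. This module emulates both from a single integer seed so
the whole pipeline (gridding, rule evaluation, automaton, validation,
calibration) is exercisable end to end:

* continuous driver layers are smooth low-frequency random surfaces with an
  optional seasonal sinusoid and small noise, rescaled into the declared
  physical range (temperature in degC, coverages and crop fractions in
  [0, 1], ...);
* categorical land-cover layers are contiguous patches obtained by
  quantile-binning a smooth surface;
* ground-truth resistance dynamics are produced by the automaton itself
  under a planted rule set, so truth is by construction within the model
  class;
* bioassay records sample cells uniformly each year; mortality falls in
  [40, 89.9] for cells whose annual truth is confirmed and [90, 100]
  otherwise, so WHO classification recovers the truth exactly, and a
  configurable label-noise probability swaps the band.

All randomness flows from the scenario seed through per-layer/per-year
``numpy`` seed sequences; identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ca_engine import StateGrid, run
from .grid import GridSpec, TimeAxis
from .io_formats import DriverStack, SusceptibilityRecord
from .rules import RuleSet, builtin_rulesets, evaluate_ruleset

__all__ = [
    "DriverSpec",
    "SyntheticScenario",
    "default_driver_specs",
    "generate_drivers",
    "generate_truth",
    "sample_records",
    "DriverStack",
]


@dataclass(frozen=True)
class DriverSpec:
    """Range and texture of one synthetic driver layer."""

    name: str
    kind: str = "continuous"  # or 'categorical'
    low: float = 0.0
    high: float = 1.0
    seasonal_amplitude: float = 0.0  # fraction of the range, peak-to-centre
    noise: float = 0.02  # sd of white noise, fraction of the range
    sparsity: float = 0.0  # fraction of the domain pinned to `low` (crops)
    n_components: int = 6  # low-frequency cosine components of the surface
    max_frequency: float = 2.0  # cycles across the grid
    static: bool = False  # constant in time (e.g. elevation)
    n_categories: int = 5  # categorical layers only

    def __post_init__(self) -> None:
        if self.low >= self.high and self.kind == "continuous":
            raise ValueError(f"driver {self.name!r}: low must be < high")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"driver {self.name!r}: unknown kind {self.kind!r}")


def default_driver_specs() -> dict[str, DriverSpec]:
    """Driver catalogue mirroring the field's usual covariates.

    Ranges are realistic for sub-Saharan settings: air temperature 12-42 degC
    with a seasonal cycle, monthly precipitation 0-300 mm, relative humidity
    20-95%, intervention coverage and crop fractions in [0, 1], population
    density 0-2000 per km^2, NDVI 0-0.9, elevation 0-2500 m (static), and a
    5-class categorical land-cover layer.
    """
    specs = [
        DriverSpec("temperature", low=12.0, high=42.0, seasonal_amplitude=0.12),
        DriverSpec("precipitation", low=0.0, high=300.0, seasonal_amplitude=0.30),
        DriverSpec("humidity", low=20.0, high=95.0, seasonal_amplitude=0.15),
        DriverSpec("itn_irs_coverage", low=0.0, high=1.0),
        DriverSpec("irrigated_rice", low=0.0, high=1.0, sparsity=0.55),
        DriverSpec("vegetables", low=0.0, high=1.0, sparsity=0.45),
        DriverSpec("cropland_fraction", low=0.0, high=1.0, sparsity=0.30),
        DriverSpec("population_density", low=0.0, high=2000.0),
        DriverSpec("ndvi", low=0.0, high=0.9, seasonal_amplitude=0.10),
        DriverSpec("elevation", low=0.0, high=2500.0, static=True),
        DriverSpec("lulc", kind="categorical", static=True, n_categories=5),
    ]
    return {s.name: s for s in specs}


@dataclass
class SyntheticScenario:
    """Everything needed to fabricate one reproducible study setting."""

    seed: int
    grid: GridSpec = field(
        default_factory=lambda: GridSpec(0.0, 0.0, n_rows=30, n_cols=30)
    )
    axis: TimeAxis = field(default_factory=lambda: TimeAxis(2000, 1, 60))
    planted_ruleset: RuleSet = field(default_factory=builtin_rulesets)
    driver_specs: dict[str, DriverSpec] = field(default_factory=default_driver_specs)
    n_records_per_year: int = 50
    label_noise: float = 0.0
    species: str = "gambiae_complex"
    insecticide_class: str = "pyrethroid"

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.n_records_per_year > self.grid.n_rows * self.grid.n_cols:
            raise ValueError("n_records_per_year exceeds the cell count")


def _smooth_surface(rng: np.random.Generator, spec: DriverSpec, shape) -> np.ndarray:
    """Sum of seeded low-frequency cosine waves, min-max scaled to [0, 1]."""
    nr, nc = shape
    ii, jj = np.meshgrid(np.arange(nr) / nr, np.arange(nc) / nc, indexing="ij")
    surf = np.zeros(shape)
    for _ in range(spec.n_components):
        u, v = rng.uniform(-spec.max_frequency, spec.max_frequency, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.3, 1.0)
        surf += amp * np.cos(2 * np.pi * (u * ii + v * jj) + phase)
    lo, hi = surf.min(), surf.max()
    return (surf - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)


def _continuous_layer(
    rng: np.random.Generator, spec: DriverSpec, grid: GridSpec, axis: TimeAxis
) -> np.ndarray:
    base = _smooth_surface(rng, spec, grid.shape)
    out = np.empty((axis.n_steps, *grid.shape))
    season_phase = rng.uniform(0, 2 * np.pi)
    for t in range(axis.n_steps):
        f = base.copy()
        if not spec.static:
            if spec.seasonal_amplitude:
                f = f + spec.seasonal_amplitude * np.cos(
                    2 * np.pi * t / 12.0 + season_phase
                )
            if spec.noise:
                f = f + rng.normal(0.0, spec.noise, size=grid.shape)
        f = np.clip(f, 0.0, 1.0)
        if spec.sparsity:
            # pin the lowest part of the surface to exactly `low`, so e.g.
            # crop fractions are genuinely absent over part of the domain
            f = np.clip(f - spec.sparsity, 0.0, 1.0) / (1.0 - spec.sparsity)
        out[t] = f
    return spec.low + out * (spec.high - spec.low)


def _categorical_layer(
    rng: np.random.Generator, spec: DriverSpec, grid: GridSpec, axis: TimeAxis
) -> np.ndarray:
    base = _smooth_surface(rng, spec, grid.shape)
    edges = np.quantile(base, np.linspace(0, 1, spec.n_categories + 1)[1:-1])
    codes = np.digitize(base, edges).astype(float)
    return np.repeat(codes[None], axis.n_steps, axis=0)


def generate_drivers(scenario: SyntheticScenario) -> DriverStack:
    """Fabricate the full driver stack for a scenario, reproducibly."""
    stack = DriverStack(grid=scenario.grid, axis=scenario.axis)
    root = np.random.SeedSequence(scenario.seed)
    streams = root.spawn(len(scenario.driver_specs))
    for ss, (name, spec) in zip(streams, sorted(scenario.driver_specs.items())):
        rng = np.random.default_rng(ss)
        if spec.kind == "categorical":
            values = _categorical_layer(rng, spec, scenario.grid, scenario.axis)
            legend = {k: f"class_{k}" for k in range(spec.n_categories)}
        else:
            values = _continuous_layer(rng, spec, scenario.grid, scenario.axis)
            legend = {}
        stack.layers[name] = values
        stack.kinds[name] = spec.kind
        if legend:
            stack.legends[name] = legend
    return stack


def generate_truth(
    drivers: DriverStack,
    planted_ruleset: RuleSet,
    seed_cells: Sequence[tuple[int, int]] | None = None,
) -> list[StateGrid]:
    """Ground-truth state sequence: the automaton run under the planted rules.

    With ``seed_cells`` omitted, the initial lattice holds the cells whose
    step-0 driver conditions already satisfy the emergence rules.
    """
    values = np.zeros(drivers.grid.shape, dtype=np.uint8)
    if seed_cells is None:
        permit = evaluate_ruleset(
            planted_ruleset.emergence_rules, drivers.at(0), shape=drivers.grid.shape
        )
        values = np.asarray(permit, dtype=np.uint8)
    else:
        for i, j in seed_cells:
            values[i, j] = 1
    seed = StateGrid(grid=drivers.grid, t=0, values=values)
    return run(seed, drivers, planted_ruleset)


def sample_records(
    truth: Sequence[StateGrid], scenario: SyntheticScenario
) -> list[SusceptibilityRecord]:
    """Draw georeferenced bioassay records consistent with the truth sequence.

    Per calendar year, ``n_records_per_year`` distinct cells are sampled
    uniformly; each record's mortality band follows the cell's annual
    (any-month) truth — [40, 89.9] when confirmed, [90, 100] otherwise — and
    is swapped with probability ``label_noise``. Record dates are uniform
    months of the year and coordinates jitter uniformly inside the cell.
    """
    grid, axis = scenario.grid, scenario.axis
    if len(truth) != axis.n_steps:
        raise ValueError("truth sequence does not cover the scenario time axis")
    root = np.random.SeedSequence([scenario.seed, 911])
    records: list[SusceptibilityRecord] = []
    for ss, year in zip(root.spawn(len(axis.years())), axis.years()):
        rng = np.random.default_rng(ss)
        steps = axis.steps_in_year(year)
        annual = np.any([truth[k].values for k in steps], axis=0)
        n_cells = grid.n_rows * grid.n_cols
        chosen = rng.choice(n_cells, size=scenario.n_records_per_year, replace=False)
        for flat in chosen:
            i, j = divmod(int(flat), grid.n_cols)
            confirmed = bool(annual[i, j])
            if rng.random() < scenario.label_noise:
                confirmed = not confirmed
            mortality = (
                rng.uniform(40.0, 89.9) if confirmed else rng.uniform(90.0, 100.0)
            )
            step_k = int(rng.choice(steps))
            _, month = axis.month_at(step_k)
            s = grid.cell_size
            records.append(
                SusceptibilityRecord(
                    x=grid.origin_x + (j + rng.uniform(0.0, 1.0)) * s,
                    y=grid.origin_y + (i + rng.uniform(0.0, 1.0)) * s,
                    year=year,
                    month=month,
                    species=scenario.species,
                    insecticide_class=scenario.insecticide_class,
                    mortality_pct=mortality,
                )
            )
    return records
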