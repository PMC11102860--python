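"""Extended cellular-automata engine for confirmed-resistance dynamics.

Each cell of the lattice holds a binary state (1 = confirmed phenotypic
insecticide resistance in the local vector population). The monthly
synchronous update combines two channels:

* **diffusion** — a cell becomes (or stays) confirmed when confirmed
  resistance is present in its closed Moore neighbourhood at time t AND the
  diffusion rules permit it under the cell's driver values at t; a cell
  counts as its own neighbour, so persistence also runs through this gate;
* **emergence** — a cell becomes confirmed regardless of its neighbourhood
  when the emergence rules permit, modelling de-novo appearance of
  resistance under locally selective conditions.

A cell for which both channels are false at t is 0 at t+1 whatever its
previous state: resistance disappears as soon as driver conditions stop
supporting it. The engine is fully deterministic; no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import binary_dilation

from .grid import GridSpec, TimeAxis
from .io_formats import DriverStack
from .rules import RuleSet, evaluate_ruleset

__all__ = ["StateGrid", "NeighborhoodSpec", "moore_neighbors", "step", "run"]


@dataclass(frozen=True)
class StateGrid:
    """Binary confirmed-resistance lattice at one time step."""

    grid: GridSpec
    t: int
    values: np.ndarray  # (n_rows, n_cols), {0, 1}

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.uint8)
        if v.shape != self.grid.shape:
            raise ValueError(f"state shape {v.shape} != grid shape {self.grid.shape}")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("state values must be 0 or 1")
        object.__setattr__(self, "values", v)

    @property
    def confirmed_cells(self) -> set[tuple[int, int]]:
        return set(zip(*np.nonzero(self.values)))


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Moore neighbourhood: cells within Chebyshev distance <= radius."""

    kind: str = "moore"
    radius: int = 1

    def __post_init__(self) -> None:
        if self.kind != "moore":
            raise ValueError(f"only the Moore neighbourhood is supported, got {self.kind!r}")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    @property
    def structure(self) -> np.ndarray:
        n = 2 * self.radius + 1
        return np.ones((n, n), dtype=bool)


def moore_neighbors(
    i: int, j: int, grid: GridSpec, radius: int = 1
) -> set[tuple[int, int]]:
    """Cells within Chebyshev distance <= radius of (i, j), edge-truncated.

    The centre cell is excluded; the grid has hard edges (no wrap-around).
    """
    if not (0 <= i < grid.n_rows and 0 <= j < grid.n_cols):
        raise ValueError(f"cell ({i}, {j}) outside grid {grid.shape}")
    return {
        (ii, jj)
        for ii in range(max(0, i - radius), min(grid.n_rows, i + radius + 1))
        for jj in range(max(0, j - radius), min(grid.n_cols, j + radius + 1))
        if (ii, jj) != (i, j)
    }


def _permissive(
    rules, drivers_at_t: Mapping[str, np.ndarray], shape: tuple[int, int]
) -> np.ndarray:
    out = evaluate_ruleset(rules, drivers_at_t, shape=shape)
    return np.broadcast_to(np.asarray(out, dtype=bool), shape)


def step(
    state: StateGrid,
    drivers_at_t: Mapping[str, np.ndarray],
    ruleset: RuleSet,
    nbhd: NeighborhoodSpec = NeighborhoodSpec(),
) -> StateGrid:
    """One synchronous update from t to t+1.

    New value of cell (i, j) is 1 iff

        (confirmed present in closed Moore neighbourhood at t
         AND diffusion rules permit at (i, j, t))
        OR emergence rules permit at (i, j, t)

    All decisions read the state at t only (double buffering).
    """
    shape = state.grid.shape
    for name, arr in drivers_at_t.items():
        if np.asarray(arr).shape not in ((), shape):
            raise ValueError(f"driver {name!r} shape {np.asarray(arr).shape} != {shape}")
    present = binary_dilation(state.values.astype(bool), structure=nbhd.structure)
    diffusion_ok = _permissive(ruleset.diffusion_rules, drivers_at_t, shape)
    emergence_ok = _permissive(ruleset.emergence_rules, drivers_at_t, shape)
    new = (present & diffusion_ok) | emergence_ok
    return StateGrid(grid=state.grid, t=state.t + 1, values=new.astype(np.uint8))


def run(
    seed: StateGrid,
    drivers: DriverStack,
    ruleset: RuleSet,
    axis: TimeAxis | None = None,
    nbhd: NeighborhoodSpec = NeighborhoodSpec(),
) -> list[StateGrid]:
    """Run the automaton over the whole time axis.

    Returns ``axis.n_steps`` state grids; element 0 is the seed and element
    k+1 is one update of element k under the drivers at step k. Deterministic
    given identical inputs.
    """
    axis = axis or drivers.axis
    if seed.grid != drivers.grid:
        raise ValueError("seed grid does not match driver stack grid")
    if axis.n_steps > drivers.axis.n_steps:
        raise ValueError("driver stack does not cover the requested time axis")
    states = [seed]
    for k in range(axis.n_steps - 1):
        states.append(step(states[-1], drivers.at(k), ruleset, nbhd=nbhd))
    return states
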