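"""WHO resistance-state classification and rasterisation of bioassay records.

Tube-bioassay mortality maps to the WHO phenotype categories: confirmed
resistance below 90% mortality at 60 min, possible resistance in [90, 98),
susceptible in [98, 100]. The automaton models only the binary
confirmed/not-confirmed state; point records are aggregated per cell-year
with an any-record-confirmed convention (one confirmed bioassay marks the
cell), the conservative surveillance reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ca_engine import StateGrid
from .exceptions import OutOfDomainError
from .grid import GridSpec, point_to_cell
from .io_formats import SusceptibilityRecord

__all__ = [
    "ResistanceState",
    "ObservedGrid",
    "classify_mortality",
    "rasterize_records",
    "initial_seed",
    "observed_to_frame",
]

logger = logging.getLogger(__name__)


class ResistanceState(Enum):
    CONFIRMED = "confirmed"
    POSSIBLE = "possible"
    SUSCEPTIBLE = "susceptible"


def classify_mortality(mortality_pct: float) -> ResistanceState:
    """WHO category for a 60-min bioassay mortality percentage.

    confirmed: < 90; possible: [90, 98); susceptible: [98, 100]. The three
    bands partition [0, 100] exhaustively.
    """
    if not 0.0 <= mortality_pct <= 100.0:
        raise ValueError(f"mortality_pct {mortality_pct} outside [0, 100]")
    if mortality_pct < 90.0:
        return ResistanceState.CONFIRMED
    if mortality_pct < 98.0:
        return ResistanceState.POSSIBLE
    return ResistanceState.SUSCEPTIBLE


@dataclass
class ObservedGrid:
    """Per-cell confirmed-resistance status for one year x species x class.

    Only cells with at least one record carry a status; all other cells are
    simply unobserved, never "absent".
    """

    grid: GridSpec
    year: int
    species: str
    insecticide_class: str
    cell_status: dict[tuple[int, int], bool] = field(default_factory=dict)
    n_skipped_outside: int = 0

    @property
    def covered_cells(self) -> set[tuple[int, int]]:
        return set(self.cell_status)

    def confirmed_cells(self) -> set[tuple[int, int]]:
        return {c for c, present in self.cell_status.items() if present}


def rasterize_records(
    records: Iterable[SusceptibilityRecord],
    grid: GridSpec,
    year: int,
    species: str,
    insecticide_class: str,
) -> ObservedGrid:
    """Aggregate point records into a per-cell observed grid for one year.

    A covered cell is confirmed-present iff any of its records classifies as
    confirmed resistance. Records outside the grid are skipped and counted.
    """
    obs = ObservedGrid(grid, year, species, insecticide_class)
    for rec in records:
        if (
            rec.year != year
            or rec.species != species
            or rec.insecticide_class != insecticide_class
        ):
            continue
        try:
            cell = point_to_cell(rec.x, rec.y, grid)
        except OutOfDomainError:
            obs.n_skipped_outside += 1
            logger.warning("record at (%s, %s) outside grid; skipped", rec.x, rec.y)
            continue
        confirmed = classify_mortality(rec.mortality_pct) is ResistanceState.CONFIRMED
        obs.cell_status[cell] = obs.cell_status.get(cell, False) or confirmed
    return obs


def initial_seed(observed: Sequence[ObservedGrid]) -> StateGrid:
    """Seed lattice from the earliest observed year.

    Every cell confirmed-present in the earliest year starts at state 1; all
    other cells (including unobserved ones) start at 0.
    """
    if not observed:
        raise ValueError("no observations to seed from")
    earliest = min(observed, key=lambda o: o.year)
    values = np.zeros(earliest.grid.shape, dtype=np.uint8)
    for (i, j) in earliest.confirmed_cells():
        values[i, j] = 1
    return StateGrid(grid=earliest.grid, t=0, values=values)


def observed_to_frame(observed: Iterable[ObservedGrid]) -> pd.DataFrame:
    """Flatten observed grids to a tidy table (i, j, year, status) for export."""
    rows = [
        {
            "i": i,
            "j": j,
            "year": o.year,
            "species": o.species,
            "insecticide_class": o.insecticide_class,
            "status": "confirmed_present" if present else "confirmed_absent",
        }
        for o in observed
        for (i, j), present in sorted(o.cell_status.items())
    ]
    return pd.DataFrame(
        rows, columns=["i", "j", "year", "species", "insecticide_class", "status"]
    )
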