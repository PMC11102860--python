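"""Accuracy validation against observed records and rule calibration.

Monthly model states are bridged to the yearly observation scale with an
any-month rule (a cell counts as predicted-confirmed for a year if it is
confirmed in at least one month of that year). Agreement is scored only at
cells that actually carry bioassay records — surveillance coverage is
sparse, and scoring unobserved cells would manufacture true negatives. The
score is plain classification accuracy

    (Tp + Tn) / (Tp + Tn + Fp + Fn)

per calendar year; years with no evaluated cells are undefined and excluded
from the mean. Calibration re-runs the automaton over an exhaustive grid of
candidate thresholds and keeps the first-encountered maximiser of mean
annual accuracy on the training years.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ca_engine import NeighborhoodSpec, StateGrid, run
from .grid import TimeAxis
from .io_formats import DriverStack
from .ir_states import ObservedGrid
from .rules import Condition, RuleSet, TransitionRule

__all__ = [
    "ConfusionCounts",
    "AccuracyReport",
    "CalibrationResult",
    "annual_prediction",
    "confusion",
    "accuracy",
    "validate",
    "calibrate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(c: ConfusionCounts) -> float:
    """Classification accuracy (Tp + Tn) / total; undefined on empty counts."""
    if c.total == 0:
        raise ValueError("accuracy undefined: no evaluated cells")
    return (c.tp + c.tn) / c.total


@dataclass
class AccuracyReport:
    """Per-year confusion counts and accuracy; mean over defined years."""

    species: str
    insecticide_class: str
    per_year: dict[int, ConfusionCounts] = field(default_factory=dict)

    def accuracy_for(self, year: int) -> float | None:
        c = self.per_year.get(year)
        return None if c is None or c.total == 0 else accuracy(c)

    @property
    def mean_accuracy(self) -> float | None:
        vals = [a for y in self.per_year if (a := self.accuracy_for(y)) is not None]
        return float(np.mean(vals)) if vals else None

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-year table; blank accuracy for years with no coverage."""
        rows = []
        for year in sorted(self.per_year):
            c = self.per_year[year]
            a = self.accuracy_for(year)
            rows.append(
                {
                    "year": year,
                    "tp": c.tp,
                    "tn": c.tn,
                    "fp": c.fp,
                    "fn": c.fn,
                    "accuracy": np.nan if a is None else a,
                }
            )
        return pd.DataFrame(rows, columns=["year", "tp", "tn", "fp", "fn", "accuracy"])

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "insecticide_class": self.insecticide_class,
            "per_year": {
                str(y): {
                    "tp": c.tp,
                    "tn": c.tn,
                    "fp": c.fp,
                    "fn": c.fn,
                    "accuracy": self.accuracy_for(y),
                }
                for y, c in sorted(self.per_year.items())
            },
            "mean_accuracy": self.mean_accuracy,
        }


def annual_prediction(
    states: Sequence[StateGrid], axis: TimeAxis, year: int
) -> np.ndarray:
    """Yearly prediction from monthly states: confirmed if 1 in any month."""
    steps = [k for k in axis.steps_in_year(year) if k < len(states)]
    if not steps:
        raise ValueError(f"no monthly states fall inside year {year}")
    return np.any([states[k].values for k in steps], axis=0)


def confusion(observed: ObservedGrid, predicted: np.ndarray) -> ConfusionCounts:
    """Confusion counts over the observed (record-carrying) cells only."""
    predicted = np.asarray(predicted)
    if predicted.shape != observed.grid.shape:
        raise ValueError(
            f"prediction shape {predicted.shape} != grid shape {observed.grid.shape}"
        )
    tp = tn = fp = fn = 0
    for (i, j), present in observed.cell_status.items():
        pred = bool(predicted[i, j])
        if present and pred:
            tp += 1
        elif present and not pred:
            fn += 1
        elif not present and pred:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def validate(
    states: Sequence[StateGrid],
    axis: TimeAxis,
    observed_by_year: Mapping[int, ObservedGrid],
    species: str = "any",
    insecticide_class: str = "any",
) -> AccuracyReport:
    """Score monthly states against yearly observed grids, year by year."""
    report = AccuracyReport(species=species, insecticide_class=insecticide_class)
    for year in sorted(observed_by_year):
        obs = observed_by_year[year]
        pred = annual_prediction(states, axis, year)
        report.per_year[year] = confusion(obs, pred)
    return report


def _apply_assignment(
    ruleset: RuleSet, assignment: Mapping[tuple[str, str, str], float]
) -> RuleSet:
    """Return a copy of the rule set with candidate thresholds substituted.

    Keys are (rule_name, driver, field) with field one of 'lower', 'upper'
    (interval ends) or 'value' (scalar thresholds). The substitution applies
    in both the diffusion and emergence lists wherever the rule name matches.
    """

    def patch_rules(rules: tuple[TransitionRule, ...]) -> tuple[TransitionRule, ...]:
        out = []
        for rule in rules:
            conds = list(rule.conditions)
            for k, cond in enumerate(conds):
                for (rname, driver, fieldname), value in assignment.items():
                    if rname != rule.name or driver != cond.driver:
                        continue
                    if cond.op == "in_interval":
                        lo, hi = cond.bounds  # type: ignore[misc]
                        if fieldname == "lower":
                            lo = value
                        elif fieldname == "upper":
                            hi = value
                        else:
                            raise KeyError(
                                f"field {fieldname!r} invalid for interval condition"
                            )
                        conds[k] = replace(cond, bounds=(lo, hi))
                    else:
                        if fieldname != "value":
                            raise KeyError(
                                f"field {fieldname!r} invalid for scalar condition"
                            )
                        conds[k] = replace(cond, bounds=value)
            out.append(replace(rule, conditions=tuple(conds)))
        return tuple(out)

    return RuleSet(
        diffusion_rules=patch_rules(ruleset.diffusion_rules),
        emergence_rules=patch_rules(ruleset.emergence_rules),
    )


@dataclass
class CalibrationResult:
    best_ruleset: RuleSet
    best_score: float
    best_assignment: dict[tuple[str, str, str], float]
    trace: pd.DataFrame  # one row per evaluated assignment


def calibrate(
    base_ruleset: RuleSet,
    candidates: Mapping[tuple[str, str, str], Sequence[float]],
    train_observed: Mapping[int, ObservedGrid],
    drivers: DriverStack,
    seed: StateGrid,
    axis: TimeAxis | None = None,
    nbhd: NeighborhoodSpec = NeighborhoodSpec(),
) -> CalibrationResult:
    """Exhaustive threshold search maximising mean annual training accuracy.

    ``candidates`` maps (rule_name, driver, field) to the finite list of
    values to try; the Cartesian product is scored in the declared iteration
    order and the first-encountered maximum wins (deterministic tie-break).
    """
    if not candidates or any(len(v) == 0 for v in candidates.values()):
        raise ValueError("candidate grid is empty")
    keys = list(candidates)
    trace_rows = []
    best: tuple[float, dict, RuleSet] | None = None
    for combo in itertools.product(*(candidates[k] for k in keys)):
        assignment = dict(zip(keys, combo))
        tuned = _apply_assignment(base_ruleset, assignment)
        states = run(seed, drivers, tuned, axis=axis, nbhd=nbhd)
        score = validate(states, axis or drivers.axis, train_observed).mean_accuracy
        score = -1.0 if score is None else score
        trace_rows.append(
            {**{f"{r}.{d}.{f}": v for (r, d, f), v in assignment.items()}, "mean_accuracy": score}
        )
        if best is None or score > best[0]:
            best = (score, assignment, tuned)
    assert best is not None
    return CalibrationResult(
        best_ruleset=best[2],
        best_score=best[0],
        best_assignment=best[1],
        trace=pd.DataFrame(trace_rows),
    )
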