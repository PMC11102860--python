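"""Declarative threshold rules over driver values.

A transition rule is a conjunction of threshold conditions on named drivers
(e.g. ``temperature in [15, 38]`` AND ``irrigated_rice > 0``). A rule set is
a disjunction of such rules: a cell's conditions permit confirmed resistance
when ANY rule holds. Two rule lists make up a :class:`RuleSet`:

* ``diffusion_rules`` gate spread from (and persistence within) the Moore
  neighbourhood;
* ``emergence_rules`` allow confirmed resistance to arise spontaneously in
  cells with permissive local conditions, away from any confirmed neighbour.

Evaluation is pure and works elementwise on whole driver layers (2-D numpy
arrays) as well as on scalar cell values. A condition on a missing or NaN
driver value evaluates to False and is logged — absence of data never
asserts resistance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .exceptions import SchemaError

__all__ = [
    "Condition",
    "TransitionRule",
    "RuleSet",
    "evaluate_condition",
    "evaluate_rule",
    "evaluate_ruleset",
    "builtin_rulesets",
    "OPS",
]

logger = logging.getLogger(__name__)

OPS = ("in_interval", "greater_than", "less_than", "greater_equal", "equals_category")

Value = Union[float, np.ndarray]


@dataclass(frozen=True)
class Condition:
    """One threshold predicate on a single driver.

    ``bounds`` is a (lower, upper) pair for ``in_interval`` (closed on both
    ends) and a single number otherwise (the threshold, or the category code
    for ``equals_category``).
    """

    driver: str
    op: str
    bounds: Union[float, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.op not in OPS:
            raise SchemaError(f"unknown op {self.op!r} in condition on {self.driver!r}")
        if self.op == "in_interval":
            try:
                lo, hi = self.bounds  # type: ignore[misc]
            except (TypeError, ValueError):
                raise SchemaError(
                    f"in_interval on {self.driver!r} needs a (lower, upper) pair"
                ) from None
            if lo > hi:
                raise SchemaError(
                    f"malformed interval [{lo}, {hi}] on {self.driver!r}: lower > upper"
                )
            object.__setattr__(self, "bounds", (float(lo), float(hi)))
        else:
            if isinstance(self.bounds, (tuple, list)):
                raise SchemaError(
                    f"op {self.op!r} on {self.driver!r} takes a single threshold"
                )
            object.__setattr__(self, "bounds", float(self.bounds))

    def to_dict(self) -> dict:
        b = list(self.bounds) if self.op == "in_interval" else self.bounds
        return {"driver": self.driver, "op": self.op, "bounds": b}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Condition":
        for key in ("driver", "op", "bounds"):
            if key not in d:
                raise SchemaError(f"condition missing {key!r}: {dict(d)!r}")
        bounds = d["bounds"]
        if isinstance(bounds, list):
            bounds = tuple(bounds)
        return cls(driver=str(d["driver"]), op=str(d["op"]), bounds=bounds)


@dataclass(frozen=True)
class TransitionRule:
    """A named conjunction of conditions for one species x insecticide class."""

    name: str
    conditions: tuple[Condition, ...]
    species: str = "any"
    insecticide_class: str = "any"

    def __post_init__(self) -> None:
        conds = tuple(self.conditions)
        if not conds:
            raise SchemaError(f"rule {self.name!r} has no conditions")
        object.__setattr__(self, "conditions", conds)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": self.species,
            "insecticide_class": self.insecticide_class,
            "conditions": [c.to_dict() for c in self.conditions],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransitionRule":
        if "name" not in d or "conditions" not in d:
            raise SchemaError(f"rule missing 'name' or 'conditions': {dict(d)!r}")
        return cls(
            name=str(d["name"]),
            conditions=tuple(Condition.from_dict(c) for c in d["conditions"]),
            species=str(d.get("species", "any")),
            insecticide_class=str(d.get("insecticide_class", "any")),
        )


@dataclass(frozen=True)
class RuleSet:
    """Diffusion-gate rules and spontaneous-emergence rules."""

    diffusion_rules: tuple[TransitionRule, ...] = ()
    emergence_rules: tuple[TransitionRule, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "diffusion_rules", tuple(self.diffusion_rules))
        object.__setattr__(self, "emergence_rules", tuple(self.emergence_rules))
        for group, rules in (
            ("diffusion_rules", self.diffusion_rules),
            ("emergence_rules", self.emergence_rules),
        ):
            names = [r.name for r in rules]
            if len(names) != len(set(names)):
                raise SchemaError(f"duplicate rule names in {group}: {names}")

    def to_dict(self) -> dict:
        return {
            "diffusion_rules": [r.to_dict() for r in self.diffusion_rules],
            "emergence_rules": [r.to_dict() for r in self.emergence_rules],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RuleSet":
        return cls(
            diffusion_rules=tuple(
                TransitionRule.from_dict(r) for r in d.get("diffusion_rules", [])
            ),
            emergence_rules=tuple(
                TransitionRule.from_dict(r) for r in d.get("emergence_rules", [])
            ),
        )

    def driver_names(self) -> set[str]:
        return {
            c.driver
            for r in self.diffusion_rules + self.emergence_rules
            for c in r.conditions
        }


def _false_like(shape) -> Value:
    return False if shape is None else np.zeros(shape, dtype=bool)


def evaluate_condition(
    cond: Condition, cell_values: Mapping[str, Value], shape=None
) -> Value:
    """Truth of one condition on scalar or array driver values.

    Interval checks are closed on both ends; category checks are exact code
    equality. Missing drivers and NaN values yield False (logged).
    """
    if cond.driver not in cell_values:
        logger.warning("driver %r missing; condition treated as False", cond.driver)
        return _false_like(shape)
    v = np.asarray(cell_values[cond.driver])
    if cond.op == "in_interval":
        lo, hi = cond.bounds  # type: ignore[misc]
        out = (v >= lo) & (v <= hi)
    elif cond.op == "greater_than":
        out = v > cond.bounds
    elif cond.op == "less_than":
        out = v < cond.bounds
    elif cond.op == "greater_equal":
        out = v >= cond.bounds
    else:  # equals_category
        out = v == cond.bounds
    if v.dtype.kind == "f":
        nan = np.isnan(v)
        if np.any(nan):
            logger.warning("NaN values for driver %r treated as False", cond.driver)
            out = out & ~nan
    return bool(out) if out.ndim == 0 else out


def evaluate_rule(
    rule: TransitionRule, cell_values: Mapping[str, Value], shape=None
) -> Value:
    """Conjunction over the rule's conditions."""
    out = None
    for cond in rule.conditions:
        c = evaluate_condition(cond, cell_values, shape=shape)
        out = c if out is None else out & c
    return out


def evaluate_ruleset(
    rules: Iterable[TransitionRule], cell_values: Mapping[str, Value], shape=None
) -> Value:
    """Disjunction over rules; an empty rule list permits nothing."""
    out = _false_like(shape)
    for rule in rules:
        out = out | evaluate_rule(rule, cell_values, shape=shape)
    return out


def builtin_rulesets(species: str = "any", insecticide_class: str = "any") -> RuleSet:
    """The three reference driver combinations permissive of confirmed IR.

    1. irrigated rice farming present;
    2. irrigated rice and vegetable farming with temperature in 15-38 degC;
    3. ITN/IRS coverage above 0.76 with vegetable farming and 15-38 degC.

    All three serve as both diffusion and emergence rules by default; pass
    a customised :class:`RuleSet` to assign them to one channel only.
    """
    rules = (
        TransitionRule(
            name="irrigated_rice",
            species=species,
            insecticide_class=insecticide_class,
            conditions=(Condition("irrigated_rice", "greater_than", 0.0),),
        ),
        TransitionRule(
            name="rice_vegetables_temperature",
            species=species,
            insecticide_class=insecticide_class,
            conditions=(
                Condition("irrigated_rice", "greater_than", 0.0),
                Condition("vegetables", "greater_than", 0.0),
                Condition("temperature", "in_interval", (15.0, 38.0)),
            ),
        ),
        TransitionRule(
            name="coverage_vegetables_temperature",
            species=species,
            insecticide_class=insecticide_class,
            conditions=(
                Condition("itn_irs_coverage", "greater_than", 0.76),
                Condition("vegetables", "greater_than", 0.0),
                Condition("temperature", "in_interval", (15.0, 38.0)),
            ),
        ),
    )
    return RuleSet(diffusion_rules=rules, emergence_rules=rules)
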