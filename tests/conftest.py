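"""Shared fixtures and independent naive oracles.

The oracles here deliberately avoid the package's vectorised code paths:
they are per-cell double loops and explicit arithmetic, so agreement with
the library is a genuine cross-check rather than a tautology.
"""

import numpy as np
import pytest

from resistca import GridSpec, RuleSet, TimeAxis


@pytest.fixture
def grid10():
    return GridSpec(origin_x=0.0, origin_y=0.0, n_rows=10, n_cols=10, cell_size=5.0)


@pytest.fixture
def axis24():
    return TimeAxis(start_year=2000, start_month=1, n_steps=24)


def naive_condition(cond, value):
    """Scalar threshold check, written independently of rules.evaluate_condition."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    if cond.op == "in_interval":
        lo, hi = cond.bounds
        return lo <= value <= hi
    if cond.op == "greater_than":
        return value > cond.bounds
    if cond.op == "less_than":
        return value < cond.bounds
    if cond.op == "greater_equal":
        return value >= cond.bounds
    if cond.op == "equals_category":
        return value == cond.bounds
    raise AssertionError(f"unknown op {cond.op}")


def naive_rules_permit(rules, drivers, i, j):
    """OR over rules of AND over conditions, reading drivers cell by cell."""
    for rule in rules:
        ok = True
        for cond in rule.conditions:
            layer = drivers.get(cond.driver)
            value = None if layer is None else float(np.asarray(layer)[i, j])
            if not naive_condition(cond, value):
                ok = False
                break
        if ok:
            return True
    return False


def naive_step(values, drivers, ruleset: RuleSet, radius: int = 1):
    """Per-cell double-loop reference implementation of the CA update."""
    nr, nc = values.shape
    new = np.zeros_like(values)
    for i in range(nr):
        for j in range(nc):
            present = False
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nr and 0 <= jj < nc and values[ii, jj]:
                        present = True
            diffusion = naive_rules_permit(ruleset.diffusion_rules, drivers, i, j)
            emergence = naive_rules_permit(ruleset.emergence_rules, drivers, i, j)
            new[i, j] = 1 if (present and diffusion) or emergence else 0
    return new


def random_ruleset(rng: np.random.Generator, driver_names=("a", "b", "c")) -> RuleSet:
    """Random OR-of-ANDs rule set over the given driver names."""
    from resistca import Condition, TransitionRule

    def random_rule(tag):
        conds = []
        for _ in range(rng.integers(1, 3)):
            name = driver_names[rng.integers(len(driver_names))]
            op = ("in_interval", "greater_than", "less_than", "greater_equal")[
                rng.integers(4)
            ]
            if op == "in_interval":
                lo, hi = sorted(rng.uniform(0, 1, size=2))
                conds.append(Condition(name, op, (lo, hi)))
            else:
                conds.append(Condition(name, op, float(rng.uniform(0, 1))))
        return TransitionRule(name=f"r{tag}", conditions=tuple(conds))

    n_diff = int(rng.integers(0, 3))
    n_emer = int(rng.integers(0, 3))
    return RuleSet(
        diffusion_rules=tuple(random_rule(f"d{k}") for k in range(n_diff)),
        emergence_rules=tuple(random_rule(f"e{k}") for k in range(n_emer)),
    )
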