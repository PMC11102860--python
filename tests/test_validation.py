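"""Annual accuracy scoring and threshold calibration."""

import numpy as np
import pytest

from resistca import (
    AccuracyReport,
    Condition,
    ConfusionCounts,
    GridSpec,
    RuleSet,
    StateGrid,
    SusceptibilityRecord,
    TimeAxis,
    TransitionRule,
    accuracy,
    annual_prediction,
    calibrate,
    confusion,
    rasterize_records,
    validate,
)
from resistca.ir_states import ObservedGrid
from resistca.validation import _apply_assignment


def states_from(arrays, grid):
    return [StateGrid(grid=grid, t=k, values=a) for k, a in enumerate(arrays)]


@pytest.fixture
def grid3():
    return GridSpec(0.0, 0.0, n_rows=3, n_cols=3)


class TestAnnualPrediction:
    def test_any_month_rule(self, grid3):
        axis = TimeAxis(2000, 1, 12)
        arrays = [np.zeros((3, 3), dtype=np.uint8) for _ in range(12)]
        arrays[2][1, 1] = 1  # confirmed in March only
        pred = annual_prediction(states_from(arrays, grid3), axis, 2000)
        assert pred[1, 1] and pred.sum() == 1

    def test_all_zero_months_predict_absent(self, grid3):
        axis = TimeAxis(2000, 1, 12)
        arrays = [np.zeros((3, 3), dtype=np.uint8) for _ in range(12)]
        pred = annual_prediction(states_from(arrays, grid3), axis, 2000)
        assert not pred.any()

    def test_year_outside_axis_rejected(self, grid3):
        axis = TimeAxis(2000, 1, 12)
        arrays = [np.zeros((3, 3), dtype=np.uint8)] * 12
        with pytest.raises(ValueError):
            annual_prediction(states_from(arrays, grid3), axis, 2005)


class TestConfusion:
    def _observed(self, grid, status):
        obs = ObservedGrid(grid, 2000, "s", "pyrethroid")
        obs.cell_status.update(status)
        return obs

    def test_counts_by_quadrant(self, grid3):
        obs = self._observed(
            grid3, {(0, 0): True, (0, 1): True, (1, 0): False, (1, 1): False}
        )
        pred = np.zeros((3, 3), dtype=bool)
        pred[0, 0] = True  # tp
        pred[1, 0] = True  # fp
        c = confusion(obs, pred)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_uncovered_cells_never_counted(self, grid3):
        obs = self._observed(grid3, {(0, 0): True, (2, 2): False})
        pred = np.ones((3, 3), dtype=bool)
        c = confusion(obs, pred)
        assert c.total == 2

    def test_grid_mismatch_rejected(self, grid3):
        obs = self._observed(grid3, {})
        with pytest.raises(ValueError):
            confusion(obs, np.zeros((4, 4), dtype=bool))


class TestAccuracy:
    @pytest.mark.parametrize(
        "counts,expected",
        [((3, 2, 0, 0), 1.0), ((0, 0, 2, 3), 0.0), ((5, 3, 1, 1), 0.8)],
    )
    def test_arithmetic(self, counts, expected):
        assert accuracy(ConfusionCounts(*counts)) == pytest.approx(expected)

    def test_empty_counts_undefined(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts())

    def test_symmetry_under_simultaneous_swap(self):
        a = accuracy(ConfusionCounts(tp=4, tn=1, fp=2, fn=3))
        b = accuracy(ConfusionCounts(tp=1, tn=4, fp=3, fn=2))
        assert a == pytest.approx(b)


class TestValidate:
    def test_mean_excludes_zero_coverage_years(self, grid3):
        axis = TimeAxis(2000, 1, 36)
        arrays = [np.zeros((3, 3), dtype=np.uint8) for _ in range(36)]
        for a in arrays:
            a[0, 0] = 1
        states = states_from(arrays, grid3)

        def obs(year, status):
            o = ObservedGrid(grid3, year, "s", "pyrethroid")
            o.cell_status.update(status)
            return o

        observed = {
            2000: obs(2000, {(0, 0): True, (1, 1): False}),  # accuracy 1.0
            2001: obs(2001, {}),  # no coverage: excluded (dash year)
            2002: obs(2002, {(0, 0): True, (1, 1): True}),  # accuracy 0.5
        }
        report = validate(states, axis, observed)
        assert report.accuracy_for(2000) == pytest.approx(1.0)
        assert report.accuracy_for(2001) is None
        assert report.accuracy_for(2002) == pytest.approx(0.5)
        assert report.mean_accuracy == pytest.approx(0.75)
        frame = report.to_frame()
        assert np.isnan(frame.loc[frame.year == 2001, "accuracy"]).all()


def _calibration_setup():
    """Planted upper temperature bound 38 on a 12x12 grid, 24 monthly steps."""
    from resistca import SyntheticScenario, generate_drivers, generate_truth, sample_records

    rule = TransitionRule(
        "rice_vegetables_temperature",
        conditions=(
            Condition("irrigated_rice", "greater_than", 0.0),
            Condition("vegetables", "greater_than", 0.0),
            Condition("temperature", "in_interval", (15.0, 38.0)),
        ),
    )
    planted = RuleSet(diffusion_rules=(rule,), emergence_rules=(rule,))
    scenario = SyntheticScenario(
        seed=77,
        grid=GridSpec(0.0, 0.0, n_rows=12, n_cols=12),
        axis=TimeAxis(2000, 1, 24),
        planted_ruleset=planted,
        n_records_per_year=40,
    )
    drivers = generate_drivers(scenario)
    truth = generate_truth(drivers, planted)
    records = sample_records(truth, scenario)
    observed = {
        y: rasterize_records(records, scenario.grid, y, scenario.species,
                             scenario.insecticide_class)
        for y in scenario.axis.years()
    }
    return planted, scenario, drivers, truth, observed


class TestCalibrate:
    def test_recovers_planted_temperature_bound(self):
        planted, scenario, drivers, truth, observed = _calibration_setup()
        candidates = {
            ("rice_vegetables_temperature", "temperature", "upper"): [30.0, 34.0, 38.0, 42.0]
        }
        result = calibrate(planted, candidates, observed, drivers, truth[0])
        planted_states = truth
        planted_score = validate(planted_states, scenario.axis, observed).mean_accuracy
        assert result.best_score >= planted_score
        assert len(result.trace) == 4

    def test_best_score_is_self_consistent(self):
        from resistca import run as run_engine

        planted, scenario, drivers, truth, observed = _calibration_setup()
        candidates = {
            ("rice_vegetables_temperature", "temperature", "upper"): [34.0, 38.0]
        }
        result = calibrate(planted, candidates, observed, drivers, truth[0])
        states = run_engine(truth[0], drivers, result.best_ruleset)
        rescore = validate(states, scenario.axis, observed).mean_accuracy
        assert result.best_score == pytest.approx(rescore)

    def test_single_candidate_returned_unchanged(self):
        planted, scenario, drivers, truth, observed = _calibration_setup()
        candidates = {
            ("rice_vegetables_temperature", "temperature", "upper"): [38.0]
        }
        result = calibrate(planted, candidates, observed, drivers, truth[0])
        assert result.best_ruleset == planted
        assert len(result.trace) == 1

    def test_tie_break_takes_first_in_iteration_order(self, grid3):
        # constant drivers make every candidate score identically
        from resistca.io_formats import DriverStack
        from resistca import run as _

        axis = TimeAxis(2000, 1, 12)
        stack = DriverStack(grid=grid3, axis=axis)
        stack.layers["x"] = np.full((12, 3, 3), 0.5)
        stack.kinds["x"] = "continuous"
        rule = TransitionRule("r", (Condition("x", "greater_than", 0.0),))
        base = RuleSet(diffusion_rules=(rule,), emergence_rules=(rule,))
        obs = ObservedGrid(grid3, 2000, "s", "pyrethroid")
        obs.cell_status[(0, 0)] = True
        seed = StateGrid(grid3, 0, np.zeros((3, 3), dtype=np.uint8))
        result = calibrate(
            base, {("r", "x", "value"): [0.1, 0.2, 0.3]}, {2000: obs}, stack, seed
        )
        assert result.best_assignment == {("r", "x", "value"): 0.1}

    def test_empty_candidate_grid_rejected(self, grid3):
        with pytest.raises(ValueError):
            calibrate(RuleSet(), {}, {}, None, None)


def test_apply_assignment_patches_both_channels():
    rule = TransitionRule(
        "r", (Condition("temperature", "in_interval", (15.0, 38.0)),)
    )
    rs = RuleSet(diffusion_rules=(rule,), emergence_rules=(rule,))
    tuned = _apply_assignment(rs, {("r", "temperature", "upper"): 42.0})
    assert tuned.diffusion_rules[0].conditions[0].bounds == (15.0, 42.0)
    assert tuned.emergence_rules[0].conditions[0].bounds == (15.0, 42.0)
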