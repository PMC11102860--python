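"""Correlation, chi-square, PCA retention and cluster reduction."""

import itertools

import numpy as np
import pytest

from resistca import (
    chi_square,
    cluster_drivers,
    pca_select,
    pearson_r,
    select_drivers,
)


def orthogonal_sign_matrix(p):
    """All +-1 combinations: columns exactly uncorrelated with zero mean."""
    return np.array(list(itertools.product((-1.0, 1.0), repeat=p)))


def duplicated_pairs_matrix():
    """v2 = v1, v4 = v3, corr(v1, v3) = 0 exactly."""
    v1 = np.array([1.0, -1.0, 1.0, -1.0])
    v3 = np.array([1.0, 1.0, -1.0, -1.0])
    return np.column_stack([v1, v1, v3, v3])


class TestPearson:
    def test_perfect_linear(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_worked_example(self):
        res = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)
        assert res.important

    def test_importance_threshold(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=500)
        noise = rng.normal(size=500)
        weak = pearson_r(x, 0.05 * x + noise)
        assert abs(weak.r) <= 0.2 and not weak.important

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 40))
        r = pearson_r(x, y).r
        assert pearson_r(y, x).r == pytest.approx(r)
        assert pearson_r(3.0 * x + 7.0, y).r == pytest.approx(r)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestChiSquare:
    def test_observed_equals_expected_gives_zero(self):
        res = chi_square([[5, 5], [5, 5]])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_worked_examples(self):
        assert chi_square([[10, 20], [20, 10]]).statistic == pytest.approx(
            6.6667, abs=1e-3
        )
        assert chi_square([[30, 0], [0, 30]]).statistic == pytest.approx(60.0)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            r, c = rng.integers(2, 6, size=2)
            obs = rng.integers(1, 50, size=(r, c)).astype(float)
            res = chi_square(obs)
            total = obs.sum()
            stat = 0.0
            for i in range(r):
                for j in range(c):
                    e = obs[i].sum() * obs[:, j].sum() / total
                    stat += (obs[i, j] - e) ** 2 / e
            assert res.statistic == pytest.approx(stat, abs=1e-9)
            assert res.df == (r - 1) * (c - 1)

    def test_permutation_invariance(self):
        obs = np.array([[3, 9, 1], [7, 2, 8]], dtype=float)
        base = chi_square(obs).statistic
        assert chi_square(obs[::-1]).statistic == pytest.approx(base)
        assert chi_square(obs[:, ::-1]).statistic == pytest.approx(base)

    def test_expected_marginals_match_observed(self):
        res = chi_square([[10, 20], [5, 30]])
        assert np.allclose(res.expected.sum(axis=0), res.observed.sum(axis=0))
        assert np.allclose(res.expected.sum(axis=1), res.observed.sum(axis=1))

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])


class TestPCASelect:
    def test_ten_independent_drivers_retain_nine_pcs(self):
        X = orthogonal_sign_matrix(10)
        rep = pca_select(X)
        assert np.allclose(rep.eigenvalues, 1.0)
        assert np.allclose(rep.proportion, 0.1)
        assert rep.retained_pc_count == 9

    def test_duplicated_pairs_retain_two_pcs_and_all_drivers(self):
        rep = pca_select(duplicated_pairs_matrix(), driver_names=list("abcd"))
        assert np.allclose(sorted(rep.eigenvalues), [0, 0, 2, 2], atol=1e-12)
        assert rep.retained_pc_count == 2
        # every driver loads at least 0.5 in magnitude on some retained PC
        assert set(rep.retained_drivers) == set("abcd")
        for name in "abcd":
            assert np.abs(rep.loadings.loc[name][:2]).max() >= 0.5 - 1e-9

    def test_cumulative_proportions_nondecreasing_and_sum_to_one(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 7))
        rep = pca_select(X)
        assert np.all(np.diff(rep.cumulative) >= -1e-12)
        assert rep.cumulative[-1] == pytest.approx(1.0, abs=1e-9)
        assert rep.eigenvalues.sum() == pytest.approx(7.0, abs=1e-9)

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            pca_select(X)


class TestClusterDrivers:
    def test_duplicate_drivers_merge_at_zero(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=100)
        X = np.column_stack([v, v, rng.normal(size=100)])
        Z, clusters = cluster_drivers(X, driver_names=["a", "b", "c"])
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)  # first merge height
        assert clusters["a"] == clusters["b"] != clusters["c"]

    def test_independent_drivers_join_near_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(5000, 2))
        Z, _ = cluster_drivers(X)
        assert Z[-1, 2] == pytest.approx(1.0, abs=0.1)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 6))
        Z, _ = cluster_drivers(X)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_anticorrelated_counts_as_close(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=200)
        X = np.column_stack([v, -v])
        Z, clusters = cluster_drivers(X)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)


class TestSelectDrivers:
    def test_single_perfect_predictor_retained(self):
        y = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        X = y.reshape(-1, 1) * 2.0 + 1.0
        rep = select_drivers(X, y, driver_names=["pressure"])
        assert rep.final_drivers == ["pressure"]
        assert rep.correlations["pressure"].important

    def test_duplicated_driver_reduced_to_one(self):
        rng = np.random.default_rng(21)
        v = rng.normal(size=200)
        y = (v > 0).astype(float)
        X = np.column_stack([v, v])
        rep = select_drivers(X, y, driver_names=["alpha", "alpha_copy"])
        assert rep.final_drivers == ["alpha"]  # lexicographic tie-break

    def test_significant_categorical_joins_selection(self):
        rng = np.random.default_rng(22)
        v = rng.normal(size=100)
        y = (v > 0).astype(float)
        rep = select_drivers(
            v.reshape(-1, 1),
            y,
            driver_names=["cont"],
            categorical_tables={"lulc": np.array([[30, 0], [0, 30]])},
        )
        assert "lulc" in rep.final_drivers
        assert rep.chi_square_results["lulc"].p_value < 0.05

    def test_unimportant_driver_dropped(self):
        rng = np.random.default_rng(23)
        y = rng.integers(0, 2, size=400).astype(float)
        X = np.column_stack([y + rng.normal(0, 0.2, 400), rng.normal(size=400)])
        rep = select_drivers(X, y, driver_names=["signal", "noise"])
        assert "signal" in rep.final_drivers
        assert "noise" not in rep.final_drivers
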