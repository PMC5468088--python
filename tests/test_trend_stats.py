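"""Cuzick's trend test against exact permutation enumeration, plus
quantile relabeling and the regression helpers."""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats

from betapop.trend_stats import (
    cuzick_trend_test,
    model_comparison,
    relabel_by_quantile,
    residual_trend,
)


def _permutation_moments(values, labels, scores):
    """Exact mean/variance of T over all label permutations (oracle)."""
    ranks = stats.rankdata(values)
    l = np.array([scores[lab] for lab in labels], float)
    ts = np.asarray(
        [float(np.sum(l[list(perm)] * ranks)) for perm in permutations(range(len(l)))]
    )
    return ts.mean(), ts.var(ddof=0)


class TestCuzickOracle:
    def test_worked_example(self):
        values = [1, 2, 3, 4, 5, 6]
        labels = [1, 1, 2, 2, 3, 3]
        res = cuzick_trend_test(values, labels)
        assert res.T == 50.0
        assert res.expected == 42.0
        assert res.variance == pytest.approx(14.0)
        assert res.z == pytest.approx(8 / np.sqrt(14.0), abs=1e-6)  # 2.138
        assert res.p == pytest.approx(0.0326, abs=5e-4)

    def test_antisymmetry_under_value_reversal(self):
        values = [1, 2, 3, 4, 5, 6]
        labels = [1, 1, 2, 2, 3, 3]
        z_fwd = cuzick_trend_test(values, labels).z
        z_rev = cuzick_trend_test(values[::-1], labels).z
        assert z_rev == pytest.approx(-z_fwd, abs=1e-12)

    @pytest.mark.parametrize(
        "values,labels",
        [
            ((1, 2, 3, 4, 5, 6), (1, 1, 2, 2, 3, 3)),
            ((3, 1, 4, 1, 5, 9, 2), (1, 1, 1, 2, 2, 3, 3)),
            ((1, 1, 2, 2, 3, 3, 4), (1, 2, 1, 2, 3, 3, 3)),  # heavy ties
            ((5, 5, 5, 1, 2), (1, 1, 2, 2, 2)),
            ((2, 4, 6, 8), (1, 2, 3, 4)),
        ],
    )
    def test_moments_match_exact_permutation_distribution(self, values, labels):
        scores = {lab: lab for lab in set(labels)}
        res = cuzick_trend_test(values, labels, scores=scores)
        mean_o, var_o = _permutation_moments(values, labels, scores)
        assert res.expected == pytest.approx(mean_o, abs=1e-10)
        assert res.variance == pytest.approx(var_o, abs=1e-10)

    def test_no_tie_variance_matches_textbook_formula(self):
        values = [3.1, 1.2, 5.6, 2.2, 9.9, 0.4, 7.7, 4.4]
        labels = [1, 1, 2, 2, 2, 3, 3, 3]
        res = cuzick_trend_test(values, labels)
        N = len(values)
        n = {1: 2, 2: 3, 3: 3}
        L1 = sum(lab * n[lab] for lab in n)
        L2 = sum(lab**2 * n[lab] for lab in n)
        var_textbook = (N + 1) / 12 * (N * L2 - L1**2)
        assert res.variance == pytest.approx(var_textbook, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        values = rng.standard_normal(60)
        labels = rng.integers(1, 5, 60)
        z1 = cuzick_trend_test(values, labels).z
        z2 = cuzick_trend_test(np.exp(values), labels).z
        assert z1 == pytest.approx(z2, abs=1e-12)

    def test_custom_score_permutation(self):
        # e.g. scores (4,1,2,3): relabeled orderings must follow the scores
        values = np.arange(12.0)
        labels = np.repeat([1, 2, 3, 4], 3)
        inc = cuzick_trend_test(values, labels).z
        perm = cuzick_trend_test(values, labels, scores={1: 4, 2: 1, 3: 2, 4: 3}).z
        assert inc > 2.0 > perm

    def test_degenerate_all_tied_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            cuzick_trend_test(np.ones(10), np.repeat([1, 2], 5))

    def test_one_tailed_halves_two_tailed_for_positive_z(self):
        values = [1, 2, 3, 4, 5, 6]
        labels = [1, 1, 2, 2, 3, 3]
        two = cuzick_trend_test(values, labels, tails=2)
        one = cuzick_trend_test(values, labels, tails=1)
        assert one.p == pytest.approx(two.p / 2)


class TestRelabelByQuantile:
    def test_eight_values_two_per_quartile(self):
        labels = relabel_by_quantile(np.arange(10, 90, 10.0))
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 3, 3, 4, 4])

    def test_monotone_transform_leaves_labels_unchanged(self, rng):
        x = rng.standard_normal(40)
        np.testing.assert_array_equal(
            relabel_by_quantile(x), relabel_by_quantile(np.tanh(x) * 100)
        )

    def test_agrees_with_sort_then_split_oracle(self, rng):
        x = rng.standard_normal(101)  # not divisible by 4
        labels = relabel_by_quantile(x)
        order = np.argsort(x, kind="stable")
        # oracle: walk the sorted values, assigning quartile by max-rank rule
        n = x.size
        oracle = np.empty(n, int)
        ranks = stats.rankdata(x, method="max")
        oracle = np.ceil(ranks * 4 / n).astype(int)
        np.testing.assert_array_equal(labels, oracle)
        sizes = np.bincount(labels)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_all_equal_raises(self):
        with pytest.raises(ValueError, match="all values equal"):
            relabel_by_quantile(np.ones(8))


class TestResidualTrend:
    def test_zero_slope_predictor_reduces_to_plain_trend(self, rng):
        mot = rng.standard_normal(80) + np.repeat([0.0, 0.1, 0.2, 0.3], 20)
        labels = np.repeat([1, 2, 3, 4], 20)
        ttt = rng.standard_normal(80)  # independent of mot
        res, slope = residual_trend(mot, ttt, labels)
        plain = cuzick_trend_test(mot, labels)
        # residualizing on an unrelated predictor barely changes Z
        assert res.z == pytest.approx(plain.z, abs=0.5)

    def test_fully_explained_mot_leaves_no_trend(self, rng):
        ttt = rng.uniform(1, 10, 200)
        mot = 0.05 * ttt  # exactly linear, no group effect
        labels = rng.integers(1, 5, 200)
        res, slope = residual_trend(mot + rng.normal(0, 1e-6, 200), ttt, labels)
        assert abs(res.z) < 2.5
        assert slope["slope"] == pytest.approx(0.05, rel=1e-3)

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError, match="constant predictor"):
            residual_trend(np.arange(10.0), np.ones(10), np.repeat([1, 2], 5))


class TestModelComparison:
    def test_duplicated_predictor_changes_nothing(self, rng):
        y = rng.standard_normal(100)
        x = rng.standard_normal(100)
        models, ftests = model_comparison(
            y,
            {"beta": x, "beta_copy": x.copy()},
            models=[("beta",), ("beta", "beta_copy")],
            nested_pairs=[(("beta",), ("beta", "beta_copy"))],
        )
        r2 = models.set_index("model")["r_squared"]
        assert r2["beta+beta_copy"] == pytest.approx(r2["beta"], abs=1e-10)
        assert ftests["F"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_superset_r2_at_least_subset(self, rng):
        y = rng.standard_normal(150)
        preds = {k: rng.standard_normal(150) for k in ("beta", "gamma", "lf")}
        models, _ = model_comparison(y, preds)
        r2 = models.set_index("model")["r_squared"]
        assert r2["beta+gamma"] >= r2["beta"] - 1e-12
        assert r2["beta+lf"] >= r2["lf"] - 1e-12

    def test_noise_predictor_rejection_rate_near_alpha(self, rng):
        # calibration: F-test on an added pure-noise predictor rejects ~5%
        n_reps, hits = 400, 0
        for _ in range(n_reps):
            y = rng.standard_normal(60)
            x1 = rng.standard_normal(60)
            x2 = rng.standard_normal(60)
            _, ftests = model_comparison(
                y,
                {"a": x1, "b": x2},
                models=[("a",), ("a", "b")],
                nested_pairs=[(("a",), ("a", "b"))],
            )
            hits += ftests["p"].iloc[0] < 0.05
        assert hits / n_reps == pytest.approx(0.05, abs=0.03)


def test_null_type_one_error_calibrated(rng):
    """Label-permutation null: rejection rate at alpha=0.05 stays nominal."""
    n, reps = 120, 1000
    values = rng.standard_normal(n)
    hits = 0
    for _ in range(reps):
        labels = rng.permutation(np.repeat([1, 2, 3, 4], n // 4))
        hits += cuzick_trend_test(values, labels).p < 0.05
    assert 0.03 <= hits / reps <= 0.07
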