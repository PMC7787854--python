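"""Statistical layer: rates, tests, logistic fits, ROC/Youden, DeLong."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2drem import stats
from t2drem.stats import (
    ContingencyTable2x2,
    DegenerateMarginError,
    EmptyGroupError,
    OneClassError,
    SeparationError,
    ZeroVarianceError,
    auc_compare,
    chi_square,
    logistic_fit,
    optimal_cutoff,
    pearson_r,
    remission_rate,
    roc_curve,
    two_sample_t,
    univariate_screen,
    youden_j,
)


class TestRemissionRate:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(33, 8, 80.49), (16, 25, 39.02), (53, 34, 60.92), (0, 7, 0.0)],
    )
    def test_row_percentages(self, a, b, expected):
        t = ContingencyTable2x2(a, b, 1, 1)
        assert remission_rate(t, group=0) == pytest.approx(expected, abs=0.005)

    def test_empty_group_raises(self):
        with pytest.raises(EmptyGroupError):
            remission_rate(ContingencyTable2x2(0, 0, 3, 4), group=0)

    def test_odds_ratio(self):
        t = ContingencyTable2x2(33, 8, 16, 25)
        assert t.odds_ratio == pytest.approx(33 * 25 / (8 * 16))


class TestChiSquare:
    def test_cpeptide_auc_split(self):
        stat, p, dof = chi_square([[33, 8], [16, 25]])
        assert stat == pytest.approx(14.66, abs=0.01)
        assert dof == 1
        assert p < 0.001

    def test_identical_proportions_give_zero(self):
        stat, p, _ = chi_square([[10, 20], [5, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_table(self):
        stat, _, dof = chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_permutation_invariance(self):
        t = [[12, 7], [3, 19]]
        s1 = chi_square(t)[0]
        s2 = chi_square([[7, 12], [19, 3]])[0]
        s3 = chi_square([[3, 19], [12, 7]])[0]
        assert s1 == pytest.approx(s2) == pytest.approx(s3)

    def test_closed_form_on_2x2(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, size=4)
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert chi_square([[a, b], [c, d]])[0] == pytest.approx(expected)

    def test_degenerate_margin(self):
        with pytest.raises(DegenerateMarginError):
            chi_square([[0, 0], [3, 4]])


class TestTTestAndPearson:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_welch_hand_example(self):
        t, _ = two_sample_t([1, 2, 3], [4, 5, 6])
        assert abs(t) == pytest.approx(3.674, abs=1e-3)

    def test_constant_samples_infinite_statistic(self):
        t, p = two_sample_t([2.0, 2.0], [5.0, 5.0])
        assert math.isinf(t) and t < 0 and p == 0.0

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
            ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_pearson(self, x, y, expected):
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(expected)

    def test_pearson_zero_variance(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestUnivariateScreen:
    def _frame(self):
        # the published C-peptide AUC split: 33/8 above vs 16/25 below
        rows = []
        for y, n, level in ((1, 33, 1.0), (0, 8, 1.0), (1, 16, 0.0), (0, 25, 0.0)):
            rows += [{"marker": level, "flat": 1.0, "y": y}] * n
        return pd.DataFrame(rows)

    def test_strong_predictor_flagged(self):
        out = univariate_screen(self._frame(), "y", {
            "marker": {"column": "marker", "kind": "binary"},
        })
        assert out["flagged"].all()
        assert out["p_value"].iloc[0] < 0.001
        rates = dict(zip(out["level"], out["remission_rate_pct"]))
        assert rates["1.0"] == pytest.approx(80.49, abs=0.005)
        assert rates["0.0"] == pytest.approx(39.02, abs=0.005)

    def test_null_predictor_not_flagged(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=200), "y": [0, 1] * 100})
        df["x"] = np.where(df.index < 100, 0.0, 1.0)  # independent of y
        out = univariate_screen(df, "y", {"x": {"column": "x", "kind": "binary"}})
        assert not out["flagged"].any()

    def test_single_level_predictor_excluded_with_reason(self):
        out = univariate_screen(self._frame(), "y", {
            "flat": {"column": "flat", "kind": "binary"},
        })
        assert out["excluded_reason"].iloc[0] == "fewer than two levels"

    def test_median_split_uses_listwise_median(self):
        df = pd.DataFrame(
            {"v": [1, 2, 3, 4, np.nan, np.nan], "y": [0, 0, 1, 1, 1, 0]}
        )
        out = univariate_screen(df, "y", {"v": {"column": "v", "kind": "median"}})
        assert set(out["level"]) == {"<=2.5", ">2.5"}
        assert (out["n_excluded"] == 2).all()


class TestLogistic:
    def _expand(self, a, b, c, d):
        x = [1.0] * (a + b) + [0.0] * (c + d)
        y = [1] * a + [0] * b + [1] * c + [0] * d
        return pd.DataFrame({"x": x}), y

    def test_single_binary_slope_equals_log_odds_ratio(self):
        X, y = self._expand(33, 8, 16, 25)
        fit = logistic_fit(X, y)
        assert fit.coef("x") == pytest.approx(math.log(33 * 25 / (8 * 16)),
                                              abs=1e-6)
        assert fit.coef("x") == pytest.approx(1.863, abs=1e-3)
        assert fit.odds_ratio("x") == pytest.approx(math.exp(fit.coef("x")))

    def test_null_predictor_coefficient_near_zero(self):
        X, y = self._expand(20, 20, 20, 20)
        fit = logistic_fit(X, y)
        assert fit.coef("x") == pytest.approx(0.0, abs=1e-8)
        low, high = fit.table.loc["x", ["ci_low", "ci_high"]]
        assert low < 1.0 < high  # CI brackets the point estimate

    def test_perfect_separation_reported_not_estimated(self):
        X = pd.DataFrame({"x": [0.0] * 10 + [1.0] * 10})
        y = [0] * 10 + [1] * 10
        with pytest.raises(SeparationError):
            logistic_fit(X, y)

    def test_converges_within_iteration_budget(self):
        X, y = self._expand(30, 12, 14, 28)
        fit = logistic_fit(X, y)
        assert fit.converged and fit.n_iter <= 25


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_curve([4, 3, 2, 1], [True, True, False, False])
        assert curve.auc == pytest.approx(1.0)
        cut = optimal_cutoff(curve)
        assert cut.j == pytest.approx(1.0)
        assert 2 <= cut.threshold < 3

    def test_pure_ties(self):
        curve = roc_curve([5, 5, 5, 5], [True, False, True, False])
        assert curve.auc == pytest.approx(0.5)
        assert optimal_cutoff(curve).j == pytest.approx(0.0)

    def test_hand_computed_auc(self):
        # pairs: (3+,2-),(3+,0-),(1+,2-),(1+,0-): 3 of 4 concordant
        curve = roc_curve([3, 2, 1, 0], [True, False, True, False])
        assert curve.auc == pytest.approx(0.75)

    def test_direction_inversion_maps_auc(self, rng):
        s = rng.normal(size=50)
        y = rng.random(50) < 0.4
        a = roc_curve(s, y).auc
        assert roc_curve(-s, y).auc == pytest.approx(1.0 - a)
        # a 'lower is positive' marker scores the same as its negation
        assert roc_curve(s, y, direction="lower").auc == pytest.approx(1.0 - a)

    def test_one_class_raises(self):
        with pytest.raises(OneClassError):
            roc_curve([1, 2, 3], [True, True, True])

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(30):
            n = int(rng.integers(10, 120))
            s = rng.choice(np.round(rng.normal(size=8), 2), size=n)  # many ties
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            assert roc_curve(s, y).auc == pytest.approx(
                roc_auc_score(y, s), abs=1e-12
            )

    @pytest.mark.parametrize(
        "sens, spec, expected",
        [(0.673, 0.758, 0.431), (1.0, 1.0, 1.0), (0.5, 0.5, 0.0)],
    )
    def test_youden(self, sens, spec, expected):
        assert youden_j(sens, spec) == pytest.approx(expected)

    def test_youden_range_violation(self):
        with pytest.raises(ValueError):
            youden_j(1.2, 0.5)

    @given(data=st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_optimal_cutoff_matches_brute_force(self, data):
        n = data.draw(st.integers(6, 40))
        s = np.array(
            data.draw(
                st.lists(
                    st.sampled_from([0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0]),
                    min_size=n, max_size=n,
                )
            )
        )
        y = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        if y.all() or not y.any():
            return
        cut = optimal_cutoff(roc_curve(s, y))
        best_j, best_t = -2.0, None
        for t in [-np.inf] + sorted(set(s)):
            sens = np.mean(s[y] > t)
            spec = np.mean(s[~y] <= t)
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        assert cut.j == pytest.approx(best_j, abs=1e-12)
        assert cut.threshold == best_t  # lowest threshold among maxima


class TestAucCompare:
    def test_self_comparison_is_null(self, rng):
        s = rng.normal(size=40)
        y = rng.random(40) < 0.5
        res = auc_compare(s, s, y)
        assert res.difference == 0.0 and res.p_value == 1.0

    def test_perfect_vs_ties(self):
        y = np.array([True] * 10 + [False] * 10)
        perfect = np.where(y, 1.0, 0.0)
        ties = np.zeros(20)
        res = auc_compare(perfect, ties, y)
        assert res.difference == pytest.approx(0.5)
        assert res.p_value < 0.05

    def test_null_scores_have_vanishing_difference(self, rng):
        # two uninformative score vectors (one a permutation of the other):
        # both AUCs concentrate at 1/2, so the difference concentrates at 0
        n = 500
        y = rng.random(n) < 0.5
        base = rng.normal(size=n)
        other = base[rng.permutation(n)]
        res = auc_compare(base, other, y)
        assert abs(res.difference) < 0.1
        assert res.p_value > 0.01

    def test_permutation_method_agrees_in_direction(self, rng):
        y = np.array([True] * 15 + [False] * 15)
        good = np.where(y, 1.0, 0.0) + rng.normal(0, 0.3, 30)
        noise = rng.normal(size=30)
        d = auc_compare(good, noise, y, method="delong")
        p = auc_compare(good, noise, y, method="permutation", n_perm=400, rng=rng)
        assert d.difference == pytest.approx(p.difference)
        assert (d.p_value < 0.05) == (p.p_value < 0.05)
        assert p.method == "permutation"

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError):
            auc_compare([1, 2, 3], [1, 2], [True, False, True])


def test_trapezoid_auc_equals_concordance_small():
    # tie-corrected Mann-Whitney on a tiny instance, counted by hand:
    # pos {2, 1}, neg {2, 0}: (2,2)->0.5, (2,0)->1, (1,2)->0, (1,0)->1
    curve = roc_curve([2, 2, 1, 0], [True, False, True, False])
    assert curve.auc == pytest.approx(2.5 / 4)
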