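"""Standardized OLS, Mann–Whitney U and the group-comparison router."""
import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

import cprkinemat as ck
from cprkinemat.config import PREDICTOR_COLUMNS
from cprkinemat.errors import ValidationError


class TestStandardizedOLS:
    def test_exact_linear_relation(self, rng):
        X = rng.normal(size=(50, 3))
        y = 2.0 + X @ [1.5, -0.5, 3.0]
        res = ck.standardized_ols(X, y)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert res.se_est == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.b, [2.0, 1.5, -0.5, 3.0], atol=1e-9)

    def test_hand_solved_six_point_dataset(self):
        """Coefficients of a 6-point, 2-predictor fit frozen from an exact
        symbolic solve of the normal equations: b = (4/9, 11/36, 59/36)."""
        X = pd.DataFrame({"x1": [0, 1, 2, 3, 4, 5], "x2": [1, 0, 2, 1, 3, 2]})
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0])
        res = ck.standardized_ols(X, y)
        assert np.allclose(res.b, [4 / 9, 11 / 36, 59 / 36], atol=1e-12)
        assert np.allclose(
            res.se_b, [0.295717026345765, 0.118937338691344, 0.212156282173882],
            atol=1e-10,
        )
        assert res.adj_r2 == pytest.approx(0.970238095238095, abs=1e-12)
        assert res.f_stat == pytest.approx(82.5, abs=1e-9)
        assert res.se_est == pytest.approx(np.sqrt(5 / 36), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_closed_form_oracle_small_n(self, seed):
        """All-random small instances (n <= 12, p = 2) against an independent
        normal-equation solve."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(7, 13))
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        res = ck.standardized_ols(X, y)
        Xd = np.column_stack([np.ones(n), X])
        b_oracle = np.linalg.inv(Xd.T @ Xd) @ Xd.T @ y
        assert np.allclose(res.b, b_oracle, atol=1e-8)

    def test_matches_statsmodels(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list(PREDICTOR_COLUMNS))
        y = X.to_numpy() @ [1.0, -2.0, 0.5, 0.0] + rng.normal(size=200)
        res = ck.standardized_ols(X, y)
        fit = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
        assert np.allclose(res.b, fit.params, atol=1e-8)
        assert np.allclose(res.se_b, fit.bse, atol=1e-8)
        assert np.allclose(res.t, fit.tvalues[1:], atol=1e-8)
        assert np.allclose(res.p, fit.pvalues[1:], atol=1e-10)
        assert res.adj_r2 == pytest.approx(fit.rsquared_adj, abs=1e-10)
        assert res.f_stat == pytest.approx(fit.fvalue, abs=1e-8)
        assert res.df == (4, 195)

    @pytest.mark.parametrize("seed", range(4))
    def test_standardization_identity(self, seed):
        """beta_j = b_j * s_xj / s_y and t_j = beta_j / se_beta_j on every fit."""
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(40, 3)) * [1.0, 50.0, 0.01]
        y = rng.normal(size=40)
        res = ck.standardized_ols(X, y)
        sx = X.std(axis=0, ddof=1)
        sy = y.std(ddof=1)
        assert np.allclose(res.beta, res.b[1:] * sx / sy, atol=1e-10)
        assert np.allclose(res.t, res.beta / res.se_beta, atol=1e-10)

    def test_collinear_columns_named(self, rng):
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": rng.normal(size=100), "c": 2.0 * x})
        with pytest.raises(ValidationError, match="c|a"):
            ck.standardized_ols(X, rng.normal(size=100))

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValidationError, match="rows"):
            ck.standardized_ols(rng.normal(size=(5, 4)), rng.normal(size=5))


def _brute_force_u(a, b):
    """Independent U oracle: direct pair counting with half-credit for ties."""
    return sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
    )


def _brute_force_p(a, b):
    """Exact two-sided p by enumerating every split of the pooled values."""
    pooled = list(a) + list(b)
    n1 = len(a)
    mu = n1 * (len(pooled) - n1) / 2.0
    obs = abs(_brute_force_u(a, b) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
        perm_u = _brute_force_u([pooled[i] for i in combo], rest)
        total += 1
        if abs(perm_u - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_complete_separation(self):
        u, p, method = ck.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert method == "exact"
        assert p == pytest.approx(_brute_force_p([1, 2, 3], [4, 5, 6]))

    def test_identical_samples_exact_p_is_one(self):
        _, p, method = ck.mann_whitney([1, 2, 3], [1, 2, 3])
        assert method == "exact"
        assert p == 1.0

    def test_small_example_matches_enumeration(self):
        a, b = [1, 3, 5], [2, 4]
        u, p, _ = ck.mann_whitney(a, b)
        assert u == _brute_force_u(a, b)
        assert p == pytest.approx(_brute_force_p(a, b))

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_equals_enumeration_oracle(self, seed):
        """U and exact p match brute-force enumeration for group sizes <= 7,
        including ties."""
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 8, size=2)
        a = rng.integers(0, 6, size=n1).astype(float)  # coarse grid forces ties
        b = rng.integers(0, 6, size=n2).astype(float)
        u, p, method = ck.mann_whitney(a, b)
        assert method == "exact"
        assert u == pytest.approx(_brute_force_u(a, b))
        assert p == pytest.approx(_brute_force_p(a, b))

    def test_u_matches_scipy_and_bounds(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=25)
        u, p, method = ck.mann_whitney(a, b)
        assert method == "normal"
        assert u == sps.mannwhitneyu(a, b, alternative="two-sided").statistic
        assert 0.0 <= u <= 30 * 25
        p_scipy = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic").pvalue
        assert p == pytest.approx(p_scipy, abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ck.mann_whitney([], [1.0])


class TestCompareGroups:
    def _table(self, deep_vals, shallow_vals, feature="pl_mm"):
        return pd.DataFrame(
            {
                feature: np.concatenate([deep_vals, shallow_vals]),
                "group": ["deep"] * len(deep_vals) + ["shallow"] * len(shallow_vals),
            }
        )

    def test_shift_alternative_detected(self, rng):
        """A +700 mm shift in the deep group's PL gives ~700 median difference
        and a small p."""
        base = rng.normal(2300, 300, size=40)
        table = self._table(base + 700.0, rng.normal(2300, 300, size=40))
        comp = ck.compare_groups(table, "pl_mm")
        assert comp.median_deep - comp.median_shallow == pytest.approx(700, abs=250)
        assert comp.p < 0.05

    def test_identical_groups_have_zero_median_difference(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        comp = ck.compare_groups(self._table(vals, vals), "pl_mm")
        assert comp.median_deep == comp.median_shallow
        assert comp.p > 0.5

    def test_single_group_table_rejected(self):
        table = pd.DataFrame({"pl_mm": [1.0, 2.0], "group": ["deep", "deep"]})
        with pytest.raises(ValidationError, match="both groups"):
            ck.compare_groups(table, "pl_mm")

    def test_normality_gate_routes_to_t(self, rng):
        table = self._table(rng.normal(10, 1, 50), rng.normal(12, 1, 50))
        comp = ck.compare_groups(table, "pl_mm")
        assert comp.test == "t"
        assert comp.t_stat is not None

    def test_skewed_data_routes_to_mannwhitney(self, rng):
        table = self._table(rng.exponential(5, 60), rng.exponential(8, 60))
        comp = ck.compare_groups(table, "pl_mm")
        assert comp.test == "mannwhitney"
        assert 0 <= comp.u_stat <= 60 * 60

    def test_calibrated_generator_group_direction_follows_beta(self, calibrated_table):
        """The generator's PL coefficient is negative, so deep rows carry the
        shorter path lengths — the partial-coefficient sign, not the marginal
        group ordering quoted alongside it."""
        table = ck.group_by_depth(calibrated_table, threshold_mm=42.0)
        comp = ck.compare_groups(table, "pl_mm")
        assert comp.median_deep < comp.median_shallow
        lkfa = ck.compare_groups(table, "lkfa")
        assert lkfa.median_deep > lkfa.median_shallow  # positive LKFA beta
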