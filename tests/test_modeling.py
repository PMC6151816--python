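"""OLS fitting, prediction, random splits, and the all-subset search."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from qsarval.exceptions import (
    InsufficientDataError,
    ParameterError,
    SingularDesignError,
    SubsetCapError,
)
from qsarval.modeling import all_subset_search, fit_mlr, predict, random_split
from qsarval.validation_internal import loo_cv

from conftest import make_dataset


class TestFitMLR:
    def test_noiseless_recovery(self, noiseless_dataset):
        X, y = noiseless_dataset
        m = fit_mlr(X, y)
        assert m.intercept == pytest.approx(3.0, abs=1e-10)
        np.testing.assert_allclose(m.coefficients, [2.0, -1.0], atol=1e-10)
        assert m.R2 == pytest.approx(1.0, abs=1e-12)
        assert m.RMSE_tr == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations(self, random_design):
        X, y = random_design
        m = fit_mlr(X, y)
        # independent oracle: solve (Xa' Xa) b = Xa' y directly
        Xa = np.column_stack([np.ones(len(X)), X.to_numpy()])
        beta = np.linalg.solve(Xa.T @ Xa, Xa.T @ y.to_numpy())
        assert m.intercept == pytest.approx(beta[0], rel=1e-10)
        np.testing.assert_allclose(m.coefficients, beta[1:], rtol=1e-10)

    def test_diagnostic_definitions(self, random_design):
        X, y = random_design
        m = fit_mlr(X, y)
        n, p = X.shape
        yv = y.to_numpy()
        resid = yv - predict(m, X)
        rss = float(resid @ resid)
        tss = float(((yv - yv.mean()) ** 2).sum())
        assert m.R2 == pytest.approx(1 - rss / tss)
        assert m.R2_adj == pytest.approx(1 - (1 - m.R2) * (n - 1) / (n - p - 1))
        assert m.RMSE_tr == pytest.approx(math.sqrt(rss / n))
        assert m.F == pytest.approx(((tss - rss) / p) / (rss / (n - p - 1)))
        # standardized coefficients: b_j * sd(x_j) / sd(y)
        np.testing.assert_allclose(
            m.standardized_coefficients,
            m.coefficients * X.std(ddof=1).to_numpy() / yv.std(ddof=1),
            rtol=1e-10,
        )

    def test_r2_equals_squared_correlation_of_fitted(self, random_design):
        X, y = random_design
        m = fit_mlr(X, y)
        r = np.corrcoef(y.to_numpy(), predict(m, X))[0, 1]
        assert m.R2 == pytest.approx(r**2, rel=1e-10)

    def test_residuals_orthogonal_to_design(self, random_design):
        X, y = random_design
        m = fit_mlr(X, y)
        resid = y.to_numpy() - predict(m, X)
        assert abs(resid.sum()) < 1e-8
        for col in X.columns:
            assert abs(resid @ X[col].to_numpy()) < 1e-8

    def test_boundary_sample_size(self, rng):
        X = pd.DataFrame(rng.standard_normal((4, 3)), columns=list("abc"))
        y = pd.Series(rng.standard_normal(4), index=X.index)
        with pytest.raises(InsufficientDataError):
            fit_mlr(X, y)  # n = p + 1

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame(rng.standard_normal((15, 2)), columns=["a", "b"])
        X["sum_ab"] = X["a"] + X["b"]
        y = pd.Series(rng.standard_normal(15), index=X.index)
        with pytest.raises(SingularDesignError, match="sum_ab"):
            fit_mlr(X, y)

    def test_rmse_ddof_option(self, random_design):
        X, y = random_design
        n, p = X.shape
        m0 = fit_mlr(X, y)
        m1 = fit_mlr(X, y, rmse_ddof=p + 1)
        assert m1.RMSE_tr == pytest.approx(m0.RMSE_tr * math.sqrt(n / (n - p - 1)))


class TestPredict:
    def test_all_zero_row_gives_intercept(self, random_design):
        X, y = random_design
        m = fit_mlr(X, y)
        row = pd.DataFrame([[0.0, 0.0, 0.0]], columns=X.columns)
        assert predict(m, row)[0] == pytest.approx(m.intercept)

    def test_training_rmse_self_consistency(self, random_design):
        X, y = random_design
        m = fit_mlr(X, y)
        rmse = np.sqrt(((y.to_numpy() - predict(m, X)) ** 2).mean())
        assert rmse == pytest.approx(m.RMSE_tr, rel=1e-10)

    def test_manual_dot_product(self, random_design):
        X, y = random_design
        m = fit_mlr(X, y)
        row = pd.DataFrame([[0.5, -1.2, 2.0]], columns=X.columns)
        by_hand = m.intercept + 0.5 * m.coefficients[0] - 1.2 * m.coefficients[1] + 2.0 * m.coefficients[2]
        assert predict(m, row)[0] == pytest.approx(by_hand, rel=1e-12)

    def test_missing_column_rejected(self, random_design):
        X, y = random_design
        m = fit_mlr(X, y)
        from qsarval.exceptions import SchemaError

        with pytest.raises(SchemaError, match="missing descriptor"):
            predict(m, X[["a", "b"]])


class TestRandomSplit:
    @pytest.mark.parametrize("n,expected_test", [(50, 10), (45, 9)])
    def test_sizes(self, rng, n, expected_test):
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"],
                         index=[f"c{i}" for i in range(n)])
        y = pd.Series(rng.standard_normal(n), index=X.index)
        ds = make_dataset(X, y)
        split = random_split(ds, 0.2, seed=7)
        assert len(split.test_ids) == expected_test
        assert len(split.train_ids) == n - expected_test

    def test_same_seed_identical(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"],
                         index=[f"c{i}" for i in range(30)])
        y = pd.Series(rng.standard_normal(30), index=X.index)
        ds = make_dataset(X, y)
        s1 = random_split(ds, 0.2, seed=11)
        s2 = random_split(ds, 0.2, seed=11)
        assert s1.assignment == s2.assignment
        s3 = random_split(ds, 0.2, seed=12)
        assert s1.assignment != s3.assignment

    def test_degenerate_fraction_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"],
                         index=[f"c{i}" for i in range(10)])
        y = pd.Series(rng.standard_normal(10), index=X.index)
        ds = make_dataset(X, y)
        with pytest.raises(ParameterError):
            random_split(ds, 0.01, seed=0)  # rounds to an empty test set
        with pytest.raises(ParameterError):
            random_split(ds, 1.2, seed=0)


class TestAllSubsetSearch:
    def test_enumeration_is_exhaustive(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 8)),
                         columns=[f"d{i}" for i in range(8)],
                         index=[f"c{i}" for i in range(30)])
        y = pd.Series(rng.standard_normal(30), index=X.index)
        res = all_subset_search(X, y, k_sub=4)
        assert res.n_evaluated == math.comb(8, 4) == 70

    def test_noiseless_generating_subset_wins(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 10)),
                         columns=[f"d{i}" for i in range(10)],
                         index=[f"c{i}" for i in range(40)])
        y = 1.0 + X["d1"] - 2 * X["d4"] + 0.5 * X["d6"] + 3 * X["d9"]
        res = all_subset_search(X, pd.Series(y, index=X.index), k_sub=4)
        assert set(res.best.descriptors) == {"d1", "d4", "d6", "d9"}
        assert res.best.R2 == pytest.approx(1.0, abs=1e-10)

    def test_full_ranking_matches_naive_enumeration(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 9)),
                         columns=[f"d{i}" for i in range(9)],
                         index=[f"c{i}" for i in range(30)])
        y = pd.Series(
            X["d0"].to_numpy() - X["d5"].to_numpy() + rng.normal(0, 0.5, 30),
            index=X.index,
        )
        res = all_subset_search(X, y, k_sub=3)
        # independent oracle: refit every subset with the generic fitter and
        # naive-loop LOO, then sort with the same tie-break
        naive = []
        for combo in itertools.combinations(X.columns, 3):
            sub = X[list(combo)]
            m = fit_mlr(sub, y)
            q2, _, _ = loo_cv(sub, y)
            naive.append((tuple(combo), m.R2, q2))
        naive.sort(key=lambda t: (-t[2], -t[1], t[0]))
        got = [(s.descriptors, s.R2, s.Q2_LOO) for s in res.ranked]
        assert [g[0] for g in got] == [nv[0] for nv in naive]
        np.testing.assert_allclose([g[1] for g in got], [nv[1] for nv in naive],
                                   rtol=1e-9)
        np.testing.assert_allclose([g[2] for g in got], [nv[2] for nv in naive],
                                   rtol=1e-9)

    def test_cap_refused_with_count(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 12)),
                         columns=[f"d{i}" for i in range(12)],
                         index=[f"c{i}" for i in range(30)])
        y = pd.Series(rng.standard_normal(30), index=X.index)
        with pytest.raises(SubsetCapError, match="495"):
            all_subset_search(X, y, k_sub=4, cap=100)
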