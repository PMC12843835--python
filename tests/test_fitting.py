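"""OLS fitting, leave-one-out validation and best-subset selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from logfm.errors import (LeverageError, SingularityError, ValidationError)
from logfm.fitting import (amemiya_pc, best_subset_search, evaluate_on_test,
                           ols_fit, press_q2, split_train_test)
from logfm.synthdata import gen_reference_table


def loo_press_oracle(X, y):
    """Explicit refit-without-point-i loop (independent of the hat-matrix route)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        Z = np.column_stack([np.ones(n - 1), X[mask]])
        beta, *_ = np.linalg.lstsq(Z, y[mask], rcond=None)
        pred = beta[0] + X[i] @ beta[1:]
        press += (y[i] - pred) ** 2
    return press


class TestOlsFit:
    def test_noise_free_line_recovered_exactly(self):
        x = np.linspace(0, 10, 20)
        fit = ols_fit(x.reshape(-1, 1), 2 + 3 * x)
        assert fit.coefficients.intercept == pytest.approx(2, abs=1e-10)
        assert fit.coefficients.coefficients["x0"] == pytest.approx(3, abs=1e-10)
        assert fit.R2 == pytest.approx(1, abs=1e-12)

    def test_orthogonal_response_gives_zero_slope(self):
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        fit = ols_fit(X, y)
        assert fit.coefficients.coefficients["x0"] == pytest.approx(0, abs=1e-12)
        assert fit.R2 == pytest.approx(0, abs=1e-12)

    def test_coefficient_recovery_within_three_se(self):
        study = gen_reference_table(n=55, sigma=0.18, seed=7)
        fit = ols_fit(study.X, study.y)
        for name, truth in study.truth.coefficients.items():
            est = fit.coefficients.coefficients[name]
            se = fit.coefficients.se[name]
            assert abs(est - truth) < 3 * se, name

    def test_rank_deficient_names_collinear_column(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["b"] = 2 * X["a"]
        with pytest.raises(SingularityError, match="b"):
            ols_fit(X, rng.normal(size=20))

    def test_constant_response_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            ols_fit(np.arange(10.0).reshape(-1, 1), np.ones(10))

    def test_refit_on_fitted_values_is_idempotent(self, study):
        fit = ols_fit(study.X, study.y)
        refit = ols_fit(study.X, fit.predict(study.X))
        assert refit.R2 == pytest.approx(1, abs=1e-10)
        for name in fit.column_names:
            assert refit.coefficients.coefficients[name] == pytest.approx(
                fit.coefficients.coefficients[name], rel=1e-8)


class TestPressQ2:
    def test_noise_free_data_gives_press_zero_q2_one(self):
        x = np.linspace(0, 5, 12)
        press, q2 = press_q2(x.reshape(-1, 1), 1 + 2 * x)
        assert press == pytest.approx(0, abs=1e-18)
        assert q2 == pytest.approx(1, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_hat_matrix_route_equals_explicit_loo(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(25, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(scale=0.3, size=25)
        press, _ = press_q2(X, y)
        assert press == pytest.approx(loo_press_oracle(X, y), rel=1e-10)

    def test_unit_leverage_rejected(self):
        # two duplicated x values plus one isolated point: the isolated
        # point determines its own fit (leverage 1)
        X = np.array([[0.0], [0.0], [1.0]])
        y = np.array([0.1, -0.1, 5.0])
        with pytest.raises(LeverageError):
            press_q2(X, y)

    def test_fit_result_invariants(self, study):
        fit = ols_fit(study.X, study.y)
        sse = float(fit.residuals @ fit.residuals)
        assert fit.R2_adj <= fit.R2
        assert fit.PRESS >= sse
        assert fit.Q2 <= fit.R2
        assert fit.RMSE >= 0


class TestAmemiyaPC:
    def test_formula_instantiation(self):
        assert amemiya_pc(1.0, 10, 2) == pytest.approx(12 / 80)

    def test_zero_sse_gives_zero(self):
        for n, p in [(10, 1), (50, 5)]:
            assert amemiya_pc(0.0, n, p) == 0.0

    def test_penalty_strictly_increases_with_p(self):
        pcs = [amemiya_pc(2.5, 30, p) for p in range(1, 30)]
        assert all(b > a for a, b in zip(pcs, pcs[1:]))

    @pytest.mark.parametrize("n, p", [(5, 5), (5, 6), (3, 0)])
    def test_invalid_dimensions_rejected(self, n, p):
        with pytest.raises(ValidationError):
            amemiya_pc(1.0, n, p)


def enumeration_oracle(X, y, min_vars, max_vars):
    """Independent brute-force subset enumeration scored by PC."""
    cols = list(X.columns)
    n = len(y)
    best, best_key = None, None
    for k in range(min_vars, max_vars + 1):
        for subset in itertools.combinations(cols, k):
            Z = np.column_stack([np.ones(n), X[list(subset)].to_numpy()])
            beta, *_ = np.linalg.lstsq(Z, np.asarray(y, float), rcond=None)
            sse = float(np.sum((y - Z @ beta) ** 2))
            pc = sse * (n + k + 1) / (n * (n - k - 1))
            key = (pc, len(subset), subset)
            if best_key is None or key < best_key:
                best, best_key = subset, key
    return best


class TestBestSubset:
    def test_true_descriptors_recovered(self):
        study = gen_reference_table(n=55, sigma=0.18, seed=3, n_nuisance=5)
        cols = list(study.descriptor_names) + [f"noise{i}" for i in range(1, 6)]
        res = best_subset_search(study.table[cols], study.y, 2, 5)
        assert set(study.descriptor_names) <= set(res.chosen.subset)
        assert res.exhaustive

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(30, 7)),
                         columns=[f"c{i}" for i in range(7)])
        y = X["c1"] - 2 * X["c4"] + rng.normal(scale=0.5, size=30)
        res = best_subset_search(X, y, 1, 4)
        assert res.chosen.subset == enumeration_oracle(X, y, 1, 4)

    def test_ranking_is_non_decreasing_in_pc(self, study):
        cols = list(study.descriptor_names)
        res = best_subset_search(study.table[cols], study.y, 2, 4)
        pcs = [c.pc for c in res.ranked]
        assert pcs == sorted(pcs)

    def test_min_vars_forces_subset_size(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"signal": rng.normal(size=40),
                          "junk1": rng.normal(size=40),
                          "junk2": rng.normal(size=40)})
        y = 3 * X["signal"] + rng.normal(scale=0.1, size=40)
        res = best_subset_search(X, y, 2, 3)
        assert len(res.chosen.subset) >= 2
        assert "signal" in res.chosen.subset

    def test_budget_exceeded_without_fallback_raises(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(30, 10)))
        with pytest.raises(ValidationError, match="budget"):
            best_subset_search(X, rng.normal(size=30), 1, 5,
                               budget=3, allow_fallback=False)

    def test_greedy_fallback_is_flagged(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 10)),
                         columns=[f"c{i}" for i in range(10)])
        y = 2 * X["c0"] + rng.normal(scale=0.1, size=40)
        res = best_subset_search(X, y, 1, 3, budget=3, allow_fallback=True)
        assert not res.exhaustive
        assert "c0" in res.chosen.subset


class TestSplit:
    def test_forty_fifteen_partition(self):
        ids = [str(i) for i in range(1, 56)]
        train, test = split_train_test(ids, 40, seed=5)
        assert (len(train), len(test)) == (40, 15)

    def test_same_seed_reproduces_partition(self):
        ids = list(range(55))
        assert split_train_test(ids, 40, 9) == split_train_test(ids, 40, 9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(3, 60), seed=st.integers(0, 1000))
    def test_disjoint_exhaustive(self, n, seed):
        ids = list(range(n))
        n_train = max(1, n // 2)
        train, test = split_train_test(ids, n_train, seed)
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)


class TestEvaluateOnTest:
    def test_perfect_fit_on_its_own_data(self):
        x = np.linspace(0, 1, 15).reshape(-1, 1)
        y = 1 + 4 * x.ravel()
        fit = ols_fit(x, y)
        stats = evaluate_on_test(fit, x, y)
        assert stats["R2"] == pytest.approx(1, abs=1e-12)
        assert stats["RMSE"] == pytest.approx(0, abs=1e-10)

    def test_negative_r2_reported_unclamped(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 1))
        fit = ols_fit(X, X.ravel() + rng.normal(scale=0.1, size=20))
        X_far = rng.normal(loc=10, size=(10, 1))
        stats = evaluate_on_test(fit, X_far, rng.normal(size=10))
        assert stats["R2"] < 0

    def test_empty_test_set_rejected(self, study):
        fit = ols_fit(study.X, study.y)
        with pytest.raises(ValidationError):
            evaluate_on_test(fit, study.X.iloc[:0], study.y[:0])
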