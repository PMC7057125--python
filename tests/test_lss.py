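"""All-subsets regression development: fitting, ranking, prediction, bias stats."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from cocktail_lss import (
    DataValidationError,
    FitError,
    LSSModel,
    PredictionError,
    best_estimates,
    bias_precision,
    enumerate_and_rank,
    fit_ols,
    predict,
    predictor_matrix,
)
from cocktail_lss.types import AUC


def normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent OLS oracle: explicit Gram-matrix solve of X'X b = X'y."""
    D = np.column_stack([np.ones(len(y)), X])
    return linalg.solve(D.T @ D, D.T @ y, assume_a="sym")


def as_frame(X, times):
    return pd.DataFrame(X, columns=list(times), index=range(1, len(X) + 1))


class TestFitOLS:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        c90 = rng.uniform(1, 10, size=10)
        X = as_frame(c90[:, None], [90])
        y = pd.Series(2.0 + 3.0 * c90, index=X.index)
        m = fit_ols(X, y, "caffeine", AUC)
        assert m.intercept == pytest.approx(2.0, abs=1e-9)
        assert m.coefficients[0] == pytest.approx(3.0, rel=1e-9)
        assert m.training_r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_gives_zero_slope_zero_r2(self):
        rng = np.random.default_rng(1)
        X = as_frame(rng.uniform(1, 10, size=(10, 1)), [120])
        y = pd.Series(np.full(10, 5.0), index=X.index)
        m = fit_ols(X, y, "caffeine", AUC)
        assert m.coefficients[0] == pytest.approx(0.0, abs=1e-9)
        assert m.training_r2 == 0.0

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_normal_equations_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(8, 17))
        k = int(rng.integers(1, 4))
        X = rng.uniform(0.1, 20.0, size=(n, k))
        beta = rng.normal(0, 2, size=k)
        y = 5.0 + X @ beta + rng.normal(0, 1.0, size=n)
        times = sorted(rng.choice([60, 90, 120, 180, 240, 300], size=k, replace=False))
        m = fit_ols(as_frame(X, times), pd.Series(y, index=range(1, n + 1)), "p", AUC)
        expected = normal_equations(X, y)
        assert np.allclose([m.intercept, *m.coefficients], expected, atol=1e-8)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(2)
        X = as_frame(rng.uniform(1, 10, size=(12, 2)), [90, 240])
        y = pd.Series(rng.uniform(10, 100, size=12), index=X.index)
        m = fit_ols(X, y, "p", AUC)
        resid = y.to_numpy() - predict(m, X).to_numpy()
        assert abs(resid.sum()) <= 1e-9 * np.abs(y).sum()

    def test_duplicate_columns_raise_fit_error_naming_times(self):
        rng = np.random.default_rng(3)
        col = rng.uniform(1, 10, size=10)
        X = as_frame(np.column_stack([col, col]), [90, 120])
        y = pd.Series(rng.uniform(0, 1, size=10), index=X.index)
        with pytest.raises(FitError, match="90"):
            fit_ols(X, y, "p", AUC)


class TestEnumerateAndRank:
    def _random_instance(self, seed, n=12, times=(60, 90, 120, 180, 240)):
        rng = np.random.default_rng(seed)
        X = as_frame(rng.uniform(0.5, 20.0, size=(n, len(times))), times)
        y = pd.Series(
            10 + X.to_numpy() @ rng.normal(0, 1, size=len(times)) + rng.normal(0, 2, n),
            index=X.index,
        )
        return X, y

    def test_subset_count(self):
        X, y = self._random_instance(0, times=(90, 120, 240))
        assert len(enumerate_and_rank(X, y, 2, "p", AUC)) == 3  # C(3,2)

    def test_ranked_order_reproduced_by_independent_refit(self):
        X, y = self._random_instance(1)
        ranked = enumerate_and_rank(X, y, 2, "p", AUC)
        refit = {
            times: fit_ols(X.loc[:, list(times)], y, "p", AUC).training_r2
            for times in itertools.combinations([60, 90, 120, 180, 240], 2)
        }
        resorted = sorted(refit, key=lambda t: -refit[t])
        assert [m.sampling_times for m in ranked] == resorted
        assert ranked[0].training_r2 == max(m.training_r2 for m in ranked)

    @pytest.mark.parametrize("seed", range(10))
    def test_nesting_monotonicity(self, seed):
        """Best (k+1)-subset training R^2 never falls below the best k-subset's."""
        X, y = self._random_instance(200 + seed)
        best = [
            enumerate_and_rank(X, y, k, "p", AUC)[0].training_r2 for k in (1, 2, 3)
        ]
        assert best[0] <= best[1] + 1e-12 and best[1] <= best[2] + 1e-12

    def test_top_model_beats_random_subsets(self):
        X, y = self._random_instance(5, times=tuple(range(60, 360, 30)))
        top = enumerate_and_rank(X, y, 2, "p", AUC)[0]
        rng = np.random.default_rng(99)
        cols = list(X.columns)
        for _ in range(1000):
            pick = sorted(rng.choice(cols, size=2, replace=False))
            r2 = fit_ols(X.loc[:, pick], y, "p", AUC).training_r2
            assert r2 <= top.training_r2 + 1e-12

    def test_pure_scaling_every_single_time_perfect_tie_broken_earliest(
        self, pure_scaling_sim
    ):
        ds = pure_scaling_sim.dataset
        met = best_estimates(ds, 1)
        y = met[met["probe"] == "caffeine"].set_index("subject_id")["value"]
        X = predictor_matrix(ds, "caffeine", 1, times=[60, 90, 120, 180, 240, 300])
        ranked = enumerate_and_rank(X, y, 1, "caffeine", AUC)
        assert all(m.training_r2 > 1 - 1e-9 for m in ranked)
        assert ranked[0].sampling_times == (60,)

    def test_k_larger_than_candidates_rejected(self):
        from cocktail_lss import ConfigurationError

        X, y = self._random_instance(6, times=(90, 240))
        with pytest.raises(ConfigurationError):
            enumerate_and_rank(X, y, 3, "p", AUC)


class TestPredict:
    def test_all_zero_input_returns_intercept(self):
        m = LSSModel("caffeine", AUC, (90, 240), -59.306, (3.030, 5.699))
        assert predict(m, {90: 0.0, 240: 0.0}).iloc[0] == pytest.approx(-59.306)

    def test_missing_time_raises(self):
        m = LSSModel("caffeine", AUC, (90, 240), 0.0, (1.0, 1.0))
        with pytest.raises(PredictionError, match="240"):
            predict(m, {90: 1.0})


class TestBiasPrecision:
    def test_perfect_agreement(self):
        best = np.array([10.0, 20.0, 30.0])
        ev = bias_precision(best, best)
        assert ev.md_pct_mean == 0 and ev.mad_pct_mean == 0 and ev.r2 == pytest.approx(1.0)

    def test_constant_relative_offset(self):
        best = np.array([10.0, 20.0, 30.0])
        ev = bias_precision(1.1 * best, best)
        assert ev.md_pct_mean == pytest.approx(10.0)
        assert ev.mad_pct_mean == pytest.approx(10.0)
        assert ev.md_pct_sd == pytest.approx(0.0, abs=1e-12)
        assert ev.mad_pct_sd == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_mixed_errors(self):
        # d = (-10, 10, 30): MD% = 10, MAD% = 50/3
        pred = np.array([90.0, 110.0, 130.0])
        best = np.array([100.0, 100.0, 100.0])
        ev = bias_precision(pred, best)
        assert ev.md_pct_mean == pytest.approx(10.0)
        assert ev.mad_pct_mean == pytest.approx(50.0 / 3.0)
        assert ev.md_pct_sd == pytest.approx(20.0)  # sample SD of (-10, 10, 30)

    def test_zero_best_estimate_rejected(self):
        with pytest.raises(DataValidationError):
            bias_precision(np.array([1.0, 2.0]), np.array([0.0, 2.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_abs_mean_bias_bounded_by_mean_absolute(self, seed):
        rng = np.random.default_rng(seed)
        best = rng.uniform(5, 50, size=16)
        pred = best * rng.uniform(0.5, 1.5, size=16)
        ev = bias_precision(pred, best)
        assert abs(ev.md_pct_mean) <= ev.mad_pct_mean + 1e-12
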