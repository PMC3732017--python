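"""Weighted trial-level regression, prediction intervals and the STE
against explicit matrix-algebra and grid-search oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import surroval as sv
from surroval.trial_level import prediction_band


def _summaries(x, y, w):
    return pd.DataFrame(
        {
            "trial_id": [f"t{i}" for i in range(len(x))],
            "n_patients": w,
            "log_hr_surrogate": x,
            "se_surrogate": 0.1,
            "log_hr_true": y,
            "se_true": 0.1,
        }
    )


def _noisy_summaries(seed=0, k=12):
    rng = np.random.default_rng(seed)
    x = rng.normal(-0.2, 0.3, k)
    y = 0.05 + 0.7 * x + rng.normal(0, 0.08, k)
    w = rng.integers(100, 2000, k)
    return _summaries(x, y, w)


def wls_normal_equations(x, y, w):
    """Independent oracle: weighted normal equations solved explicitly."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    resid = y - X @ beta
    ybar = np.sum(w * y) / np.sum(w)
    r2 = 1 - (resid @ W @ resid) / ((y - ybar) @ W @ (y - ybar))
    return beta, r2


class TestFitTrialRegression:
    def test_collinear_points_give_perfect_fit(self, collinear_summaries):
        model = sv.fit_trial_regression(collinear_summaries, n_bootstrap=0)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.residual_variance == pytest.approx(0.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.1, abs=1e-10)
        assert model.slope == pytest.approx(0.8, abs=1e-10)

    def test_three_trial_fixture_matches_normal_equations(self):
        x = np.array([-0.2, 0.0, 0.4])
        y = np.array([-0.1, 0.0, 0.1])
        w = np.array([100.0, 200.0, 100.0])
        model = sv.fit_trial_regression(_summaries(x, y, w), n_bootstrap=0)
        beta, r2 = wls_normal_equations(x, y, w)
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        assert model.slope == pytest.approx(beta[1], abs=1e-10)
        assert model.r_squared == pytest.approx(r2, abs=1e-10)

    def test_noisy_fit_matches_normal_equations(self):
        df = _noisy_summaries(1)
        model = sv.fit_trial_regression(df, n_bootstrap=0)
        beta, r2 = wls_normal_equations(
            df["log_hr_surrogate"].to_numpy(),
            df["log_hr_true"].to_numpy(),
            df["n_patients"].to_numpy(dtype=float),
        )
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        assert model.slope == pytest.approx(beta[1], abs=1e-10)
        assert model.r_squared == pytest.approx(r2, abs=1e-10)

    def test_no_association_gives_small_r_squared(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.3, 20)
        y = rng.normal(0, 0.1, 20)
        model = sv.fit_trial_regression(_summaries(x, y, np.full(20, 100)), n_bootstrap=0)
        assert model.r_squared < 0.3

    def test_r_squared_invariant_to_weight_rescaling(self):
        df = _noisy_summaries(3)
        a = sv.fit_trial_regression(df, n_bootstrap=0)
        df2 = df.assign(n_patients=df["n_patients"] * 7)
        b = sv.fit_trial_regression(df2, n_bootstrap=0)
        assert a.r_squared == pytest.approx(b.r_squared, abs=1e-12)
        assert a.slope == pytest.approx(b.slope, abs=1e-12)

    def test_bootstrap_ci_brackets_point_estimate(self):
        df = _noisy_summaries(4)
        model = sv.fit_trial_regression(df, n_bootstrap=500, seed=0)
        assert model.ci_low <= model.r_squared <= model.ci_high

    def test_bootstrap_is_seed_deterministic(self):
        df = _noisy_summaries(5)
        a = sv.fit_trial_regression(df, n_bootstrap=200, seed=7)
        b = sv.fit_trial_regression(df, n_bootstrap=200, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_too_few_trials_rejected(self):
        df = _noisy_summaries(6).head(2)
        with pytest.raises(ValueError, match="at least 3"):
            sv.fit_trial_regression(df)

    def test_event_count_weighting_supported(self, trial_summaries):
        by_patients = sv.fit_trial_regression(trial_summaries, n_bootstrap=0)
        by_events = sv.fit_trial_regression(
            trial_summaries, weight_col="n_events_true", n_bootstrap=0
        )
        assert np.isfinite(by_events.r_squared)
        # same trials, different weighting: estimates close but not identical
        assert by_events.slope != by_patients.slope

    def test_constant_surrogate_effects_rejected(self):
        df = _summaries(np.zeros(5), np.linspace(0, 1, 5), np.full(5, 100))
        with pytest.raises(ValueError, match="unidentifiable"):
            sv.fit_trial_regression(df)


class TestPredictionInterval:
    def test_matches_brute_force_hat_matrix(self):
        df = _noisy_summaries(7)
        model = sv.fit_trial_regression(df, n_bootstrap=0)
        x = df["log_hr_surrogate"].to_numpy()
        y = df["log_hr_true"].to_numpy()
        w_raw = df["n_patients"].to_numpy(dtype=float)
        w = w_raw / w_raw.mean()
        X = np.column_stack([np.ones_like(x), x])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        resid = y - X @ beta
        s2 = (resid @ W @ resid) / (len(x) - 2)
        for x0 in (-0.4, 0.0, 0.25):
            xv = np.array([1.0, x0])
            lev = xv @ np.linalg.inv(X.T @ W @ X) @ xv
            half = stats.t.ppf(0.975, len(x) - 2) * np.sqrt(s2 * (1 + lev))
            pred = xv @ beta
            lo, hi, p = sv.prediction_interval(model, x0)
            assert p == pytest.approx(pred, abs=1e-10)
            assert lo == pytest.approx(pred - half, abs=1e-10)
            assert hi == pytest.approx(pred + half, abs=1e-10)

    def test_collapses_for_collinear_fit(self, collinear_summaries):
        model = sv.fit_trial_regression(collinear_summaries, n_bootstrap=0)
        lo, hi, pred = sv.prediction_interval(model, -0.2)
        assert lo == pytest.approx(pred, abs=1e-8)
        assert hi == pytest.approx(pred, abs=1e-8)
        assert pred == pytest.approx(0.1 + 0.8 * -0.2, abs=1e-10)

    def test_narrowest_at_weighted_mean_of_surrogate_effects(self):
        df = _noisy_summaries(8)
        model = sv.fit_trial_regression(df, n_bootstrap=0)
        xbar = np.average(model.x, weights=model.weights)
        grid = np.linspace(model.x.min() - 0.5, model.x.max() + 0.5, 101)
        widths = [
            sv.prediction_interval(model, g)[1] - sv.prediction_interval(model, g)[0]
            for g in grid
        ]
        w_at_mean = (
            sv.prediction_interval(model, xbar)[1]
            - sv.prediction_interval(model, xbar)[0]
        )
        assert w_at_mean <= min(widths) + 1e-12

    def test_larger_new_trial_narrows_interval(self):
        df = _noisy_summaries(9)
        model = sv.fit_trial_regression(df, n_bootstrap=0)
        lo1, hi1, _ = sv.prediction_interval(model, 0.0, new_weight=model.mean_weight)
        lo2, hi2, _ = sv.prediction_interval(model, 0.0, new_weight=10 * model.mean_weight)
        assert hi2 - lo2 < hi1 - lo1

    def test_invalid_level_rejected(self):
        df = _noisy_summaries(10)
        model = sv.fit_trial_regression(df, n_bootstrap=0)
        with pytest.raises(ValueError):
            sv.prediction_interval(model, 0.0, level=1.0)

    def test_band_is_tabulated_interval(self):
        df = _noisy_summaries(11)
        model = sv.fit_trial_regression(df, n_bootstrap=0)
        band = prediction_band(model, np.array([-0.2, 0.0]))
        lo, hi, pred = sv.prediction_interval(model, -0.2)
        assert band.loc[0, "pi_low"] == pytest.approx(lo)
        assert band.loc[0, "prediction"] == pytest.approx(pred)


class TestSurrogateThresholdEffect:
    def test_degenerate_variance_unit_slope_gives_one(self):
        x = np.linspace(-0.5, 0.3, 8)
        model = sv.fit_trial_regression(
            _summaries(x, x.copy(), np.full(8, 100)), n_bootstrap=0
        )
        ste = sv.surrogate_threshold_effect(model)
        assert ste.defined
        assert ste.ste_hr == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_search_oracle(self):
        df = _noisy_summaries(12)
        model = sv.fit_trial_regression(df, n_bootstrap=0)
        ste = sv.surrogate_threshold_effect(model)
        assert ste.defined
        grid = np.arange(np.log(0.2), np.log(1.5), 1e-4)
        upper = np.array([sv.prediction_interval(model, g)[1] for g in grid])
        crossing = grid[np.searchsorted(upper > 0, True)]
        assert ste.ste_hr == pytest.approx(np.exp(crossing), abs=1e-3)

    def test_ste_decreases_as_residual_variance_grows(self):
        from dataclasses import replace

        df = _noisy_summaries(13)
        model = sv.fit_trial_regression(df, n_bootstrap=0)
        prev = sv.surrogate_threshold_effect(model).ste_hr
        for factor in (2.0, 5.0, 10.0):
            noisier = replace(
                model, residual_variance=model.residual_variance * factor
            )
            ste = sv.surrogate_threshold_effect(noisier)
            if not ste.defined:
                # threshold dropped below the search bracket: stricter than
                # any in-bracket value, which still respects monotonicity
                assert "above 0" in ste.reason
                break
            assert ste.ste_hr < prev
            prev = ste.ste_hr

    def test_inverted_slope_undefined_with_reason(self):
        rng = np.random.default_rng(14)
        x = np.linspace(-0.4, 0.3, 8)
        model = sv.fit_trial_regression(
            _summaries(x, -0.5 * x + rng.normal(0, 0.01, 8), np.full(8, 100)),
            n_bootstrap=0,
        )
        ste = sv.surrogate_threshold_effect(model)
        assert not ste.defined
        assert "inverted" in ste.reason

    def test_hopeless_model_undefined_with_reason(self):
        rng = np.random.default_rng(15)
        x = np.linspace(-0.4, 0.3, 8)
        y = 0.5 + 0.5 * x + rng.normal(0, 0.3, 8)  # OS effects all harmful
        model = sv.fit_trial_regression(_summaries(x, y, np.full(8, 100)), n_bootstrap=0)
        ste = sv.surrogate_threshold_effect(model)
        if model.slope > 0:
            assert not ste.defined
            assert "bracket" in ste.reason
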