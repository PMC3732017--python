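"""Trial-level surrogacy: weighted regression of treatment effects, R²,
prediction intervals and the surrogate threshold effect.

Each trial contributes a point (log HR on the surrogate, log HR on overall
survival). The trial-level model is ordinary weighted least squares of the
OS effect on the surrogate effect, weighted by trial size (patient counts),
with an intercept. The estimation-error covariance of the per-trial log HRs
is deliberately ignored — the measurement-error-adjusted meta-analytic
model exists but is a different estimand; plain size-weighted WLS is the
transparent default here.

R² is the weighted coefficient of determination; its confidence interval is
a trial-level nonparametric bootstrap (percentile), which respects the
small number of trials typical of surrogacy meta-analyses.

The prediction interval for a *new* trial with surrogate effect x0 is the
classical WLS interval

    yhat(x0)  +/-  t_{K-2}  *  sqrt( sigma2 * (1/w0 + x0' (X'WX)^-1 x0) )

with weights normalised to mean 1, so the default new-trial weight w0 = 1
corresponds to a trial of average size.

The surrogate threshold effect (STE) is the minimum treatment effect on the
surrogate needed before the model predicts a non-zero OS benefit: the
largest surrogate hazard ratio at which the upper 95% prediction limit for
the OS log hazard ratio reaches 0. It is found by root-finding on the upper
prediction limit over HR_S in [0.2, 1.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "TrialLevelResult",
    "SteResult",
    "fit_trial_regression",
    "prediction_interval",
    "surrogate_threshold_effect",
    "prediction_band",
]


@dataclass(frozen=True)
class TrialLevelResult:
    """Fitted trial-level surrogacy model."""

    intercept: float
    slope: float
    residual_variance: float
    r_squared: float
    ci_low: float
    ci_high: float
    n_trials: int
    weights: np.ndarray  # normalised to mean 1
    mean_weight: float  # raw mean trial size
    x: np.ndarray  # surrogate log hazard ratios
    cov_unscaled: np.ndarray  # (X'WX)^-1 under normalised weights
    include_intercept: bool
    n_bootstrap: int

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "residual_variance": self.residual_variance,
            "r_squared": self.r_squared,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_trials": self.n_trials,
            "mean_weight": self.mean_weight,
            "include_intercept": self.include_intercept,
            "n_bootstrap": self.n_bootstrap,
        }


def _design(x: np.ndarray, include_intercept: bool) -> np.ndarray:
    return sm.add_constant(x) if include_intercept else x.reshape(-1, 1)


def _wls_r_squared(y, fitted, w) -> float:
    resid = y - fitted
    ybar = np.average(y, weights=w)
    tss = float(np.sum(w * (y - ybar) ** 2))
    rss = float(np.sum(w * resid**2))
    return 1.0 - rss / tss


def _closed_form_r_squared(x, y, w) -> float:
    # weighted simple regression in closed form; used only by the bootstrap
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    fitted = ybar + slope * (x - xbar)
    rss = np.sum(w * (y - fitted) ** 2)
    tss = np.sum(w * (y - ybar) ** 2)
    return 1.0 - rss / tss


def fit_trial_regression(
    summaries: pd.DataFrame,
    include_intercept: bool = True,
    weight_col: str = "n_patients",
    n_bootstrap: int = 2000,
    seed: int | None = None,
) -> TrialLevelResult:
    """Size-weighted least squares of OS effects on surrogate effects.

    ``summaries`` needs columns ``log_hr_surrogate``, ``log_hr_true`` and
    the weight column (default ``n_patients``). Requires at least three
    trials and non-degenerate surrogate effects.
    """
    k = len(summaries)
    if k < 3:
        raise ValueError(f"at least 3 trials are required, got {k}")
    x = summaries["log_hr_surrogate"].to_numpy(dtype=float)
    y = summaries["log_hr_true"].to_numpy(dtype=float)
    w_raw = summaries[weight_col].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(w_raw).all()):
        raise ValueError("trial summaries contain non-finite values")
    if np.any(w_raw <= 0):
        raise ValueError("weights must be positive")
    if np.allclose(x, x[0]):
        raise ValueError("surrogate effects are constant; slope unidentifiable")

    mean_w = float(w_raw.mean())
    w = w_raw / mean_w
    design = _design(x, include_intercept)
    fit = sm.WLS(y, design, weights=w).fit()
    params = np.asarray(fit.params, dtype=float)
    if include_intercept:
        intercept, slope = float(params[0]), float(params[1])
    else:
        intercept, slope = 0.0, float(params[0])
    fitted = design @ params
    df_resid = k - design.shape[1]
    if df_resid <= 0:
        raise ValueError("not enough trials for residual degrees of freedom")
    residual_variance = float(np.sum(w * (y - fitted) ** 2) / df_resid)
    r_squared = _wls_r_squared(y, fitted, w)
    cov_unscaled = np.asarray(fit.normalized_cov_params, dtype=float)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_bootstrap)
        filled = 0
        attempts = 0
        while filled < n_bootstrap and attempts < 50 * n_bootstrap:
            attempts += 1
            idx = rng.integers(0, k, size=k)
            xb = x[idx]
            if np.allclose(xb, xb[0]):
                continue  # degenerate resample: slope unidentifiable
            boot[filled] = _closed_form_r_squared(xb, y[idx], w_raw[idx])
            filled += 1
        ci_low, ci_high = np.percentile(boot[:filled], [2.5, 97.5])
    else:
        ci_low = ci_high = r_squared

    return TrialLevelResult(
        intercept=intercept,
        slope=slope,
        residual_variance=residual_variance,
        r_squared=float(r_squared),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_trials=k,
        weights=w,
        mean_weight=mean_w,
        x=x,
        cov_unscaled=cov_unscaled,
        include_intercept=include_intercept,
        n_bootstrap=int(n_bootstrap),
    )


def _x0_vector(model: TrialLevelResult, x0: float) -> np.ndarray:
    return np.array([1.0, x0]) if model.include_intercept else np.array([x0])


def prediction_interval(
    model: TrialLevelResult,
    log_hr_surrogate_new: float,
    level: float = 0.95,
    new_weight: float | None = None,
) -> tuple[float, float, float]:
    """95% (by default) prediction interval for a new trial's OS log HR.

    ``new_weight`` is the new trial's size on the raw scale; by default the
    weighted-mean trial size of the fitted model is used. Returns
    ``(low, high, prediction)`` on the log hazard ratio scale.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly in (0, 1)")
    x0 = float(log_hr_surrogate_new)
    w0 = 1.0 if new_weight is None else float(new_weight) / model.mean_weight
    if w0 <= 0:
        raise ValueError("new_weight must be positive")
    xv = _x0_vector(model, x0)
    pred = model.intercept + model.slope * x0
    leverage = float(xv @ model.cov_unscaled @ xv)
    var = model.residual_variance * (1.0 / w0 + leverage)
    df = model.n_trials - (2 if model.include_intercept else 1)
    tq = stats.t.ppf(0.5 + level / 2.0, df)
    half = tq * np.sqrt(var)
    return float(pred - half), float(pred + half), float(pred)


def prediction_band(
    model: TrialLevelResult, grid: np.ndarray, level: float = 0.95
) -> pd.DataFrame:
    """Prediction band over a grid of surrogate log HRs (for plotting)."""
    rows = [
        (x, *prediction_interval(model, float(x), level=level)) for x in grid
    ]
    return pd.DataFrame(
        rows, columns=["log_hr_surrogate", "pi_low", "pi_high", "prediction"]
    )


@dataclass(frozen=True)
class SteResult:
    """Surrogate threshold effect on the hazard-ratio scale."""

    ste_hr: float  # nan when undefined
    reason: str | None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.ste_hr)


def surrogate_threshold_effect(
    model: TrialLevelResult,
    level: float = 0.95,
    bracket: tuple[float, float] = (0.2, 1.5),
) -> SteResult:
    """Minimum surrogate treatment effect that predicts a non-zero OS effect.

    Root of the upper prediction limit (as a function of the surrogate log
    hazard ratio) over HR_S in ``bracket``. A future trial whose CI for the
    surrogate effect falls entirely below the STE would be predicted to
    improve overall survival. Undefined (with a reason) when the slope is
    non-positive or the upper limit does not cross zero in the bracket.
    """
    if model.slope <= 0:
        return SteResult(float("nan"), "effect direction inverted (slope <= 0)")
    lo, hi = np.log(bracket[0]), np.log(bracket[1])

    def upper(x: float) -> float:
        return prediction_interval(model, x, level=level)[1]

    f_lo, f_hi = upper(lo), upper(hi)
    if f_lo > 0 and f_hi > 0:
        return SteResult(
            float("nan"),
            "upper prediction limit stays above 0 over the bracket "
            "(no surrogate effect in range predicts an OS benefit)",
        )
    if f_lo < 0 and f_hi < 0:
        return SteResult(
            float("nan"),
            "upper prediction limit stays below 0 over the bracket",
        )
    if f_lo == 0.0:
        return SteResult(float(np.exp(lo)), None)
    root = brentq(upper, lo, hi, xtol=1e-12)
    return SteResult(float(np.exp(root)), None)
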