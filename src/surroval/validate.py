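"""Internal validation of the trial-level surrogacy model.

Two checks mirror standard practice in surrogate-endpoint meta-analyses:

* **Leave-one-trial-out cross-validation** — each trial is removed, the
  size-weighted regression is refitted on the rest, and the removed trial's
  observed OS effect is compared with the 95% prediction interval at its
  surrogate effect. The headline summary is "m of K trials inside".
  The left-out trial's prediction weight defaults to its *own* size (the
  trial is known when predicting it); the weighted-mean-size convention is
  available via ``new_weight="mean"``.

* **Fixed-horizon sensitivity analysis** — all patients are administratively
  censored at an early horizon on the surrogate (e.g. 3-year DFS or 2-year
  PFS) and a later horizon on overall survival (e.g. 5 years), and the
  trial-level analysis is recomputed. This emulates the information
  actually available at the time an early readout would be used. Horizons
  at or beyond the maximum follow-up reproduce the unrestricted analysis
  bit-identically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .endpoints import censor_table_at_horizon, derive_endpoint_table
from .survival import summarize_trials
from .trial_level import TrialLevelResult, fit_trial_regression, prediction_interval

__all__ = ["LOOResult", "loo_validate", "loo_summary", "sensitivity_fixed_horizon", "horizon_sweep"]

logger = logging.getLogger("surroval")


@dataclass(frozen=True)
class LOOResult:
    trial_id: str
    observed_log_hr_true: float
    predicted_log_hr_true: float
    pi_low: float
    pi_high: float
    inside: bool


def loo_validate(
    summaries: pd.DataFrame,
    level: float = 0.95,
    new_weight: str = "own",
    include_intercept: bool = True,
) -> list[LOOResult]:
    """Leave-one-trial-out prediction of each trial's OS treatment effect.

    For every trial the model is refitted on the remaining trials and the
    held-out trial's observed OS log HR is checked against the prediction
    interval at its surrogate log HR. ``new_weight`` is ``"own"`` (default:
    the held-out trial's size) or ``"mean"`` (the refitted model's mean
    size). Requires at least 4 trials so each refit keeps 3.

    When a refit's surrogate effects are constant (exchangeable trials) the
    slope is unidentifiable and an intercept-only weighted model is used
    for that prediction instead.
    """
    if len(summaries) < 4:
        raise ValueError("leave-one-out needs at least 4 trials")
    if new_weight not in ("own", "mean"):
        raise ValueError("new_weight must be 'own' or 'mean'")
    results = []
    for i in range(len(summaries)):
        row = summaries.iloc[i]
        rest = summaries.drop(summaries.index[i])
        w0 = float(row["n_patients"]) if new_weight == "own" else None
        x_rest = rest["log_hr_surrogate"].to_numpy(dtype=float)
        try:
            if np.allclose(x_rest, x_rest[0]):
                lo, hi, pred = _intercept_only_prediction(rest, level, w0)
            else:
                model = fit_trial_regression(
                    rest, include_intercept=include_intercept, n_bootstrap=0
                )
                lo, hi, pred = prediction_interval(
                    model,
                    float(row["log_hr_surrogate"]),
                    level=level,
                    new_weight=w0,
                )
        except ValueError as exc:
            raise ValueError(
                f"leave-one-out refit failed for trial {row['trial_id']!r}: {exc}"
            ) from exc
        obs = float(row["log_hr_true"])
        results.append(
            LOOResult(
                trial_id=str(row["trial_id"]),
                observed_log_hr_true=obs,
                predicted_log_hr_true=pred,
                pi_low=lo,
                pi_high=hi,
                inside=bool(lo <= obs <= hi),
            )
        )
    return results


def _intercept_only_prediction(rest, level, new_weight):
    """Weighted mean model for refits with constant surrogate effects."""
    from scipy import stats

    y = rest["log_hr_true"].to_numpy(dtype=float)
    w_raw = rest["n_patients"].to_numpy(dtype=float)
    w = w_raw / w_raw.mean()
    k = len(y)
    pred = float(np.average(y, weights=w))
    sigma2 = float(np.sum(w * (y - pred) ** 2) / (k - 1))
    w0 = 1.0 if new_weight is None else new_weight / w_raw.mean()
    var = sigma2 * (1.0 / w0 + 1.0 / np.sum(w))
    half = stats.t.ppf(0.5 + level / 2.0, k - 1) * np.sqrt(var)
    return pred - half, pred + half, pred


def loo_summary(results: list[LOOResult]) -> dict:
    """Containment summary: how many observed OS effects fell inside."""
    n_inside = sum(r.inside for r in results)
    return {
        "n_trials": len(results),
        "n_inside": n_inside,
        "containment_fraction": n_inside / len(results) if results else float("nan"),
    }


def loo_table(results: list[LOOResult]) -> pd.DataFrame:
    """Per-trial table on the hazard-ratio scale (plot-ready)."""
    return pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in results],
            "observed_hr": np.exp([r.observed_log_hr_true for r in results]),
            "predicted_hr": np.exp([r.predicted_log_hr_true for r in results]),
            "pi_low_hr": np.exp([r.pi_low for r in results]),
            "pi_high_hr": np.exp([r.pi_high for r in results]),
            "inside": [r.inside for r in results],
        }
    )


def sensitivity_fixed_horizon(
    records: pd.DataFrame,
    surrogate: str,
    surrogate_horizon: float,
    os_horizon: float,
    include_intercept: bool = True,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> TrialLevelResult:
    """Trial-level analysis with endpoints censored at fixed horizons.

    Every patient is censored at ``surrogate_horizon`` years on the
    surrogate endpoint and at ``os_horizon`` years on overall survival,
    per-trial hazard ratios are recomputed, and the size-weighted
    regression refitted. ``inf`` horizons reproduce the unrestricted
    analysis exactly.
    """
    if not (surrogate_horizon > 0 and os_horizon > 0):
        raise ValueError("horizons must be positive")
    if surrogate_horizon > os_horizon:
        warnings.warn(
            "surrogate horizon exceeds OS horizon; the usual design uses an "
            "earlier surrogate readout",
            stacklevel=2,
        )
    long_df = derive_endpoint_table(records, endpoints=(surrogate, "os"))
    max_fup = float(records["time_last_followup"].max())
    if np.isfinite(surrogate_horizon) and surrogate_horizon > max_fup:
        warnings.warn(
            "surrogate horizon exceeds the longest follow-up; restriction is "
            "a no-op",
            stacklevel=2,
        )
    surr = censor_table_at_horizon(
        long_df[long_df["endpoint"] == surrogate], surrogate_horizon
    )
    osdf = censor_table_at_horizon(long_df[long_df["endpoint"] == "os"], os_horizon)
    summaries = summarize_trials(
        pd.concat([surr, osdf], ignore_index=True), surrogate
    )
    return fit_trial_regression(
        summaries,
        include_intercept=include_intercept,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def horizon_sweep(
    records: pd.DataFrame,
    surrogate: str,
    surrogate_horizons,
    os_horizon: float,
    **kwargs,
) -> pd.DataFrame:
    """R² of the fixed-horizon analysis over a grid of surrogate cutoffs.

    Supports the exploratory question of how early the surrogate readout
    can be taken while still tracking the unrestricted trial-level
    association.
    """
    rows = []
    for h in surrogate_horizons:
        model = sensitivity_fixed_horizon(records, surrogate, h, os_horizon, **kwargs)
        rows.append(
            {
                "surrogate_horizon": h,
                "r_squared": model.r_squared,
                "slope": model.slope,
                "n_trials": model.n_trials,
            }
        )
    return pd.DataFrame(rows)
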