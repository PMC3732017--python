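"""Assembly of the full per-comparison surrogacy report.

A *comparison* is one treatment question across a set of randomised trials
(e.g. chemotherapy vs none) with one candidate surrogate endpoint. The
report collects everything the two-level validation produces — the
individual-level copula correlation, the trial-level weighted regression
with its R² and surrogate threshold effect, the leave-one-trial-out
containment summary and the fixed-horizon sensitivity fit — plus verbal
classification labels on the conventional scale for squared correlations:

    > 0.90          excellent
    (0.75, 0.90]    very good
    (0.50, 0.75]    good
    (0.25, 0.50]    moderate
    <= 0.25         poor

Full precision is always serialised; two-decimal display is a presentation
concern only (rounding squared correlations near 1 produces degenerate
printed intervals).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .copula import IndividualLevelResult, fit_copula
from .endpoints import derive_endpoint_table
from .survival import summarize_trials
from .trial_level import (
    SteResult,
    TrialLevelResult,
    fit_trial_regression,
    surrogate_threshold_effect,
)
from .validate import loo_summary, loo_validate

__all__ = ["classify_correlation", "SurrogacyReport", "build_report"]

_SCALE = (
    (0.90, "excellent"),
    (0.75, "very good"),
    (0.50, "good"),
    (0.25, "moderate"),
)


def classify_correlation(value: float) -> str:
    """Verbal label for a squared correlation (individual ρ² or trial R²).

    Bins are half-open from above: a value must be *strictly* higher than a
    cutpoint to earn its label, so 0.75 is "good" and 0.25 is "poor".
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"squared correlation must lie in [0, 1], got {value}")
    for cut, label in _SCALE:
        if value > cut:
            return label
    return "poor"


@dataclass(frozen=True)
class SurrogacyReport:
    """All results for one (comparison, surrogate endpoint) pair."""

    comparison: str
    surrogate: str
    true_endpoint: str
    individual: IndividualLevelResult
    trial: TrialLevelResult
    ste: SteResult
    loo: dict
    fixed_horizon: TrialLevelResult | None
    individual_label: str
    trial_label: str
    provenance: dict

    def to_dict(self) -> dict:
        d = {
            "comparison": self.comparison,
            "surrogate": self.surrogate,
            "true_endpoint": self.true_endpoint,
            "individual": self.individual.to_dict(),
            "trial": self.trial.to_dict(),
            "ste_hr": self.ste.ste_hr,
            "ste_reason": self.ste.reason,
            "loo": self.loo,
            "fixed_horizon": (
                self.fixed_horizon.to_dict() if self.fixed_horizon else None
            ),
            "individual_label": self.individual_label,
            "trial_label": self.trial_label,
            "provenance": self.provenance,
        }
        return _jsonify(d)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def build_report(
    records: pd.DataFrame,
    comparison: str,
    surrogate: str = "dfs",
    true_endpoint: str = "os",
    copula_family: str = "clayton",
    surrogate_horizon: float | None = 3.0,
    os_horizon: float | None = 5.0,
    n_bootstrap_individual: int = 200,
    n_bootstrap_trial: int = 2000,
    seed: int | None = None,
) -> SurrogacyReport:
    """Run the full two-level validation chain on one comparison.

    ``records`` is the per-patient table; the chain derives endpoints,
    estimates per-trial hazard ratios, fits the individual-level copula on
    pooled patients, fits the trial-level weighted regression with its STE,
    leaves each trial out once, and repeats the trial-level fit under
    fixed-horizon censoring (skipped when either horizon is None).
    Deterministic for a fixed ``seed``.
    """
    n_trials = records["trial_id"].nunique()
    if n_trials < 3:
        raise ValueError(
            f"comparison {comparison!r} has {n_trials} trials; at least 3 are "
            "required for the trial-level regression"
        )
    errors = []
    long_df = derive_endpoint_table(records, endpoints=(surrogate, true_endpoint))
    surr_df = long_df[long_df["endpoint"] == surrogate]
    os_df = long_df[long_df["endpoint"] == true_endpoint]

    # rows within an endpoint follow the input patient order, so the two
    # slices are aligned patient-by-patient
    individual = fit_copula(
        surr_df["time"].to_numpy(),
        surr_df["event"].to_numpy(),
        os_df["time"].to_numpy(),
        os_df["event"].to_numpy(),
        family=copula_family,
        n_bootstrap=n_bootstrap_individual,
        seed=seed,
    )

    summaries = summarize_trials(long_df, surrogate, true_endpoint)
    if len(summaries) < 3:
        raise ValueError(
            f"stage trial_level: only {len(summaries)} trials remain after "
            "excluding monotone-likelihood trials"
        )
    trial = fit_trial_regression(
        summaries, n_bootstrap=n_bootstrap_trial, seed=seed
    )
    ste = surrogate_threshold_effect(trial)
    loo = (
        loo_summary(loo_validate(summaries))
        if len(summaries) >= 4
        else {"n_trials": len(summaries), "n_inside": None, "containment_fraction": None}
    )

    fixed = None
    if surrogate_horizon is not None and os_horizon is not None:
        from .validate import sensitivity_fixed_horizon

        fixed = sensitivity_fixed_horizon(
            records, surrogate, surrogate_horizon, os_horizon
        )

    provenance = {
        "individual": "surroval.copula.fit_copula",
        "trial": "surroval.trial_level.fit_trial_regression",
        "ste_hr": "surroval.trial_level.surrogate_threshold_effect",
        "loo": "surroval.validate.loo_validate",
        "fixed_horizon": "surroval.validate.sensitivity_fixed_horizon",
        "trial_summaries": "surroval.survival.summarize_trials",
        "endpoints": "surroval.endpoints.derive_endpoint_table",
        "n_trials_used": int(len(summaries)),
        "horizons": [surrogate_horizon, os_horizon],
    }
    return SurrogacyReport(
        comparison=comparison,
        surrogate=surrogate,
        true_endpoint=true_endpoint,
        individual=individual,
        trial=trial,
        ste=ste,
        loo=loo,
        fixed_horizon=fixed,
        individual_label=classify_correlation(individual.rho_squared),
        trial_label=classify_correlation(np.clip(trial.r_squared, 0.0, 1.0)),
        provenance=provenance,
    )
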