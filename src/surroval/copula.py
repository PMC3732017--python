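"""Individual-level surrogacy: rank correlation under censoring via a copula.

The association between a candidate surrogate endpoint and overall survival
*within patients* is estimated with a two-stage semiparametric copula model:

1. the marginal survival function of each endpoint is estimated by
   Kaplan-Meier and evaluated at every patient's observation time, giving a
   pseudo-sample ``(u_i, v_i)`` of survival probabilities;
2. the association parameter theta of an archimedean copula (Clayton or
   Gumbel) is estimated by maximising the censored pseudo-likelihood, whose
   per-patient contribution depends on the censoring pattern:

   ====================  =========================================
   both events            copula density  c(u, v)
   surrogate event only   partial derivative  dC/du
   OS event only          partial derivative  dC/dv
   both censored          copula value  C(u, v)
   ====================  =========================================

   (u, v are *survival* probabilities, i.e. the survival copula is fitted.)

Theta converts to Kendall's tau in closed form (Clayton: tau = theta/(theta+2);
Gumbel: tau = 1 - 1/theta) and to Spearman's rho by 2-D Gauss-Legendre
quadrature of ``12 * integral(C) - 3``. The reported individual-level
surrogacy measure is rho squared; its confidence interval comes from a
patient-level nonparametric bootstrap (percentile method), since with tens
of thousands of patients analytic intervals are degenerate to the printed
precision anyway.

The family is a reported modelling choice, not an estimate: Clayton
(lower-tail dependent) is the default, Gumbel (upper-tail dependent) the
alternative; fitting both brackets the behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .survival import km_survival_at
from .simulate import tau_from_theta

__all__ = [
    "IndividualLevelResult",
    "fit_copula",
    "copula_cdf",
    "copula_log_density",
    "copula_log_du",
    "spearman_from_theta",
    "censored_copula_loglik",
]

_MIN_PAIRS = 50

# optimisation runs on x = log(theta) for Clayton (theta > 0) and
# x = log(theta - 1) for Gumbel (theta > 1); the bounds below correspond to
# Kendall tau from ~2e-4 to ~0.995 for both families
_X_LO, _X_HI = -9.0, 6.0


@dataclass(frozen=True)
class IndividualLevelResult:
    """Copula association between a surrogate endpoint and overall survival."""

    family: str
    theta: float
    kendall_tau: float
    spearman_rho: float
    rho_squared: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_bootstrap: int
    at_boundary: bool

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "theta": self.theta,
            "kendall_tau": self.kendall_tau,
            "spearman_rho": self.spearman_rho,
            "rho_squared": self.rho_squared,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pairs": self.n_pairs,
            "n_bootstrap": self.n_bootstrap,
            "at_boundary": self.at_boundary,
        }


# ---------------------------------------------------------------------------
# copula functions (u, v are survival probabilities in (0, 1))
# ---------------------------------------------------------------------------

def _clayton_log_a(theta: float, u, v):
    # log(u^-theta + v^-theta - 1) without overflow at large theta
    a = -theta * np.log(u)
    b = -theta * np.log(v)
    m = np.maximum(a, b)
    return m + np.log(np.exp(a - m) + np.exp(b - m) - np.exp(-m))


def _gumbel_log_sum(theta: float, x, y):
    # log(x^theta + y^theta) without overflow at large theta
    a = theta * np.log(x)
    b = theta * np.log(y)
    m = np.maximum(a, b)
    return m + np.log1p(np.exp(np.minimum(a, b) - m))


def copula_cdf(family: str, theta: float, u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if family == "independence":
        return u * v
    if family == "clayton":
        return np.exp(-_clayton_log_a(theta, u, v) / theta)
    if family == "gumbel":
        x, y = -np.log(u), -np.log(v)
        s = np.exp(_gumbel_log_sum(theta, x, y) / theta)
        return np.exp(-s)
    raise ValueError(f"unknown copula family {family!r}")


def copula_log_du(family: str, theta: float, u, v):
    """log of dC(u,v)/du."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if family == "clayton":
        log_a = _clayton_log_a(theta, u, v)
        return -(theta + 1.0) * np.log(u) - (1.0 / theta + 1.0) * log_a
    if family == "gumbel":
        x, y = -np.log(u), -np.log(v)
        log_sum = _gumbel_log_sum(theta, x, y)
        s = np.exp(log_sum / theta)
        return -s + (theta - 1.0) * np.log(x) + (1.0 / theta - 1.0) * log_sum - np.log(u)
    raise ValueError(f"unknown copula family {family!r}")


def copula_log_density(family: str, theta: float, u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if family == "clayton":
        log_a = _clayton_log_a(theta, u, v)
        return (
            np.log1p(theta)
            - (theta + 1.0) * (np.log(u) + np.log(v))
            - (1.0 / theta + 2.0) * log_a
        )
    if family == "gumbel":
        x, y = -np.log(u), -np.log(v)
        log_sum = _gumbel_log_sum(theta, x, y)
        s = np.exp(log_sum / theta)
        return (
            -s
            + (theta - 1.0) * (np.log(x) + np.log(y))
            - np.log(u)
            - np.log(v)
            + (2.0 / theta - 2.0) * log_sum
            + np.log1p((theta - 1.0) / s)
        )
    raise ValueError(f"unknown copula family {family!r}")


def censored_copula_loglik(family, theta, u, v, d_surr, d_os) -> float:
    """Censored-data pseudo-log-likelihood of the copula at theta.

    ``d_surr``/``d_os`` are event indicators; ``u``/``v`` the Kaplan-Meier
    survival probabilities at each patient's surrogate/OS time.
    """
    both = d_surr & d_os
    only_s = d_surr & ~d_os
    only_t = ~d_surr & d_os
    none = ~d_surr & ~d_os
    ll = 0.0
    if both.any():
        ll += float(copula_log_density(family, theta, u[both], v[both]).sum())
    if only_s.any():
        ll += float(copula_log_du(family, theta, u[only_s], v[only_s]).sum())
    if only_t.any():
        # dC/dv by symmetry of the archimedean families
        ll += float(copula_log_du(family, theta, v[only_t], u[only_t]).sum())
    if none.any():
        ll += float(np.log(copula_cdf(family, theta, u[none], v[none])).sum())
    return ll


def _theta_from_x(family: str, x: float) -> float:
    return float(np.exp(x)) if family == "clayton" else 1.0 + float(np.exp(x))


def spearman_from_theta(family: str, theta: float, n_nodes: int = 64) -> float:
    """Spearman's rho of the copula, 12*integral(C(u,v) du dv) - 3.

    2-D tensor Gauss-Legendre quadrature on the unit square; 64 nodes per
    axis resolve the integrand well below 1e-6 for the implemented families.
    """
    if family == "independence":
        return 0.0
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    uu, vv = np.meshgrid(u, u, indexing="ij")
    c = copula_cdf(family, theta, uu, vv)
    integral = float(w @ c @ w)
    return 12.0 * integral - 3.0


# ---------------------------------------------------------------------------
# two-stage fit
# ---------------------------------------------------------------------------

def _pseudo_observations(surr_time, surr_event, os_time, os_event, n):
    u = km_survival_at(surr_time, surr_event, surr_time)
    v = km_survival_at(os_time, os_event, os_time)
    # keep survival probabilities off 0/1 so copula terms stay finite
    eps = 1.0 / (2.0 * n)
    return np.clip(u, eps, 1.0 - eps), np.clip(v, eps, 1.0 - eps)


def _fit_theta(family, u, v, d_surr, d_os) -> tuple[float, bool]:
    res = minimize_scalar(
        lambda x: -censored_copula_loglik(
            family, _theta_from_x(family, x), u, v, d_surr, d_os
        ),
        bounds=(_X_LO, _X_HI),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"copula fit failed to converge: {res.message}")
    at_boundary = res.x < _X_LO + 0.05 or res.x > _X_HI - 0.05
    return _theta_from_x(family, res.x), at_boundary


def fit_copula(
    surr_time,
    surr_event,
    os_time,
    os_event,
    family: str = "clayton",
    n_bootstrap: int = 200,
    seed: int | None = None,
) -> IndividualLevelResult:
    """Two-stage censored-copula estimate of individual-level surrogacy.

    Parameters
    ----------
    surr_time, surr_event:
        Surrogate-endpoint times (years) and event indicators, one per patient.
    os_time, os_event:
        Overall-survival times and event indicators, aligned to the same
        patients.
    family:
        ``"clayton"`` (default), ``"gumbel"``, or ``"independence"`` (the
        null model; returns zero association without fitting).
    n_bootstrap:
        Patient-level bootstrap replicates for the rho-squared percentile
        CI; 0 disables the interval (returns the point estimate for both
        bounds).
    seed:
        Seed for the bootstrap resampling.

    Returns
    -------
    IndividualLevelResult
        With ``at_boundary`` set when the association parameter hit the
        optimisation bracket (e.g. comonotone input pairs).
    """
    surr_time = np.asarray(surr_time, dtype=float)
    surr_event = np.asarray(surr_event).astype(bool)
    os_time = np.asarray(os_time, dtype=float)
    os_event = np.asarray(os_event).astype(bool)
    n = surr_time.size
    if not (surr_event.size == os_time.size == os_event.size == n):
        raise ValueError("all four input arrays must have equal length")
    if n < _MIN_PAIRS:
        raise ValueError(f"at least {_MIN_PAIRS} pairs are required, got {n}")
    if not surr_event.any() or not os_event.any():
        raise ValueError("each margin needs at least one observed event")

    if family == "independence":
        return IndividualLevelResult(
            family, float("nan"), 0.0, 0.0, 0.0, 0.0, 0.0, n, 0, False
        )

    def point_estimate(st, se, ot, oe):
        u, v = _pseudo_observations(st, se, ot, oe, st.size)
        theta, boundary = _fit_theta(family, u, v, se, oe)
        rho = spearman_from_theta(family, theta)
        return theta, boundary, rho

    theta, at_boundary, rho = point_estimate(surr_time, surr_event, os_time, os_event)
    tau = tau_from_theta(family, theta)
    rho_sq = rho * rho

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            if not surr_event[idx].any() or not os_event[idx].any():
                boot[b] = np.nan
                continue
            _, _, rho_b = point_estimate(
                surr_time[idx], surr_event[idx], os_time[idx], os_event[idx]
            )
            boot[b] = rho_b * rho_b
        ci_low, ci_high = np.nanpercentile(boot, [2.5, 97.5])
    else:
        ci_low = ci_high = rho_sq

    return IndividualLevelResult(
        family,
        float(theta),
        float(tau),
        float(rho),
        float(rho_sq),
        float(ci_low),
        float(ci_high),
        n,
        int(n_bootstrap),
        bool(at_boundary),
    )
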