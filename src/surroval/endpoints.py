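"""Endpoint derivation from raw event histories.

Three analysis endpoints are derived from each patient's event history:

* **overall survival (OS)** — time to death from any cause; patients alive
  at the last visit are censored at last follow-up;
* **DFS/PFS** — time to the first event among locoregional recurrence or
  progression, distant recurrence or progression, and death; censored at
  last follow-up when no event is documented;
* **locoregional control** — time to the first locoregional event; patients
  with distant progression or death first, or with no documented event, are
  censored at the date of distant progression, death, or last follow-up.

Conventions (documented because competing choices exist in the field):
a tie between a locoregional event and distant progression or death at the
same time counts as a locoregional *event* (events take precedence over
censoring at equal times); under fixed-horizon censoring, an event exactly
at the horizon is retained — only patients whose time extends strictly
beyond the horizon are censored there. All times are years.

Functions operate either on a single :class:`~surroval.simulate.SubjectRecord`
(returning an :class:`EndpointObservation`) or, vectorised, on the
per-patient table, returning the long-format endpoint table
``(trial_id, arm, endpoint, time, event)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import SubjectRecord

__all__ = [
    "ENDPOINTS",
    "EndpointObservation",
    "derive_overall_survival",
    "derive_dfs_pfs",
    "derive_locoregional_control",
    "censor_at_horizon",
    "derive_endpoint_table",
    "censor_table_at_horizon",
    "years_from_months",
]

ENDPOINTS = ("os", "dfs", "pfs", "locoregional_control")

#: DFS and PFS share one derivation (recurrence vs progression is a naming
#: difference between the operable and locally advanced settings)
_ALIASES = {"pfs": "dfs"}


@dataclass(frozen=True)
class EndpointObservation:
    """One derived time-to-event observation.

    ``event`` is True when the endpoint event was observed at ``time``;
    otherwise ``time`` is a right-censoring time.
    """

    endpoint: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        if self.time < 0:
            raise ValueError("time must be nonnegative")


def years_from_months(t):
    """Convert month-valued durations to the package's year unit."""
    return np.asarray(t, dtype=float) / 12.0


def derive_overall_survival(record: SubjectRecord) -> EndpointObservation:
    """Time from randomisation to death from any cause.

    Earlier locoregional or distant events do not affect OS. Patients alive
    at the last visit are censored at last follow-up.
    """
    if record.event_death:
        return EndpointObservation("os", record.time_death, True)
    return EndpointObservation("os", record.time_last_followup, False)


def derive_dfs_pfs(record: SubjectRecord, name: str = "dfs") -> EndpointObservation:
    """Time to the first of locoregional event, distant event, or death.

    A tie among event types is still a single first event. With no
    documented event the patient is censored at last follow-up.
    """
    observed = [
        t
        for t in (record.time_locoregional, record.time_distant, record.time_death)
        if t is not None
    ]
    if observed:
        return EndpointObservation(name, min(observed), True)
    return EndpointObservation(name, record.time_last_followup, False)


def derive_locoregional_control(record: SubjectRecord) -> EndpointObservation:
    """Time to the first locoregional event.

    Patients whose distant progression or death comes first, or who have no
    locoregional event, are censored at the earliest of distant progression,
    death, and last follow-up. A locoregional event tied with a distant
    event or death counts as an event.
    """
    competing = [
        t for t in (record.time_distant, record.time_death) if t is not None
    ]
    censor_time = min(competing + [record.time_last_followup])
    if record.event_locoregional and record.time_locoregional <= censor_time:
        return EndpointObservation(
            "locoregional_control", record.time_locoregional, True
        )
    return EndpointObservation("locoregional_control", censor_time, False)


def censor_at_horizon(
    obs: EndpointObservation, horizon: float
) -> EndpointObservation:
    """Administratively censor one observation at a fixed horizon.

    Observations extending strictly beyond the horizon become censored at
    the horizon; events exactly at the horizon are kept. Idempotent.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    if obs.time > horizon:
        return replace(obs, time=float(horizon), event=False)
    return obs


# ---------------------------------------------------------------------------
# vectorised table-level versions
# ---------------------------------------------------------------------------

def _derive_columns(df: pd.DataFrame, endpoint: str) -> tuple[np.ndarray, np.ndarray]:
    t_loco = df["time_locoregional"].to_numpy(dtype=float)
    t_dist = df["time_distant"].to_numpy(dtype=float)
    t_death = df["time_death"].to_numpy(dtype=float)
    t_fup = df["time_last_followup"].to_numpy(dtype=float)
    kind = _ALIASES.get(endpoint, endpoint)
    if kind == "os":
        event = ~np.isnan(t_death)
        time = np.where(event, t_death, t_fup)
    elif kind == "dfs":
        first = np.fmin(np.fmin(t_loco, t_dist), t_death)
        event = ~np.isnan(first)
        time = np.where(event, first, t_fup)
    elif kind == "locoregional_control":
        censor = np.fmin(np.fmin(t_dist, t_death), t_fup)
        event = ~np.isnan(t_loco) & (t_loco <= censor)
        time = np.where(event, t_loco, censor)
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return time, event


def derive_endpoint_table(
    df: pd.DataFrame, endpoints: tuple[str, ...] = ("os", "dfs", "locoregional_control")
) -> pd.DataFrame:
    """Derive endpoints for every patient in a per-patient table.

    Returns the long-format table with one row per (patient, endpoint):
    columns ``trial_id, arm, endpoint, time, event``. Row order within an
    endpoint follows the input table.
    """
    frames = []
    for ep in endpoints:
        time, event = _derive_columns(df, ep)
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": df["trial_id"].to_numpy(),
                    "arm": df["arm"].to_numpy(),
                    "endpoint": ep,
                    "time": time,
                    "event": event.astype(np.int64),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def censor_table_at_horizon(
    long_df: pd.DataFrame, horizon: float
) -> pd.DataFrame:
    """Vectorised :func:`censor_at_horizon` on a long-format endpoint table.

    ``horizon=inf`` returns values bit-identical to the input.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    out = long_df.copy()
    time = out["time"].to_numpy(dtype=float)
    event = out["event"].to_numpy()
    beyond = time > horizon
    out["time"] = np.where(beyond, float(horizon), time)
    out["event"] = np.where(beyond, 0, event).astype(event.dtype)
    return out
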