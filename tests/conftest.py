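import numpy as np
import pandas as pd
import pytest

import surroval as sv


def make_record(loco=None, dist=None, death=None, fup=10.0, trial="t0", arm=0):
    return sv.SubjectRecord(
        trial_id=trial,
        arm=arm,
        time_last_followup=fup,
        time_locoregional=loco,
        time_distant=dist,
        time_death=death,
    )


def concordance_tau(x, y):
    """Brute-force pairwise-concordance Kendall tau-a (independent oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    n = len(x)
    return float(np.triu(dx * dy, 1).sum() / (n * (n - 1) / 2))


@pytest.fixture(scope="session")
def meta_records():
    cfg = sv.SimulationConfig(
        n_trials=10, patients_per_trial=300, copula_tau=0.5, seed=42
    )
    return sv.simulate_meta_analysis(cfg)


@pytest.fixture(scope="session")
def history_records():
    cfg = sv.SimulationConfig(n_trials=10, patients_per_trial=300, seed=43)
    return sv.simulate_event_history(cfg)


@pytest.fixture(scope="session")
def trial_summaries(history_records):
    long_df = sv.derive_endpoint_table(history_records, endpoints=("dfs", "os"))
    return sv.summarize_trials(long_df, "dfs")


@pytest.fixture()
def collinear_summaries():
    """Ten trials exactly on the line y = 0.1 + 0.8 x."""
    x = np.linspace(-0.5, 0.3, 10)
    return pd.DataFrame(
        {
            "trial_id": [f"t{i}" for i in range(10)],
            "n_patients": np.linspace(100, 1000, 10).astype(int),
            "log_hr_surrogate": x,
            "se_surrogate": 0.1,
            "log_hr_true": 0.1 + 0.8 * x,
            "se_true": 0.1,
        }
    )
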