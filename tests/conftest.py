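import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ibdclaims import SimulationConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_encounters(rows):
    """Build an encounter frame from (person_id, date, source, icd_version, code) tuples."""
    df = pd.DataFrame(rows, columns=["person_id", "date", "source", "icd_version", "code"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def gate_frame(day_offsets, sources, start="2000-01-01"):
    """IBD-mapped encounter frame for gate tests, dated start + offsets days."""
    base = np.datetime64(start, "D")
    dates = base + np.asarray(day_offsets, dtype="int64").astype("timedelta64[D]")
    return pd.DataFrame({"date": dates, "source": list(sources)})


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate cohort under the default (paper-like) generator settings."""
    cfg = SimulationConfig(seed=42, n_persons=8_000, background_encounter_rate=1.0)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """High-contact, noise-free cohort where ascertainment should be near-perfect."""
    cfg = SimulationConfig(
        seed=99,
        n_persons=20_000,
        code_noise_prob=0.0,
        claims_per_year_post_onset=8.0,
        hospitalization_prob_per_year=0.5,
        background_encounter_rate=0.0,
    )
    return cfg, simulate_cohort(cfg)
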