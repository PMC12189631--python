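import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from awsproc.io import ADGTable, MeasurementWindow
from awsproc.simulate import SimConfig, default_windows

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def window():
    """One 7-day window starting Mon 2019-02-11, mid-date Thu 2019-02-14."""
    return MeasurementWindow("Feb", datetime.date(2019, 2, 11))


@pytest.fixture
def windows():
    return default_windows()


@pytest.fixture
def adg_table():
    return ADGTable(entries=((250.0, 0.7), (300.0, 1.0), (350.0, 0.9)))


@pytest.fixture
def small_sim_config():
    """Small, fast herd for pipeline-level tests."""
    return SimConfig(n_animals=8, seed=11)


def make_records(rows):
    """rows: (animal_id, iso timestamp, weight, concurrent) tuples."""
    df = pd.DataFrame(rows, columns=["animal_id", "timestamp", "weight_kg", "concurrent_forage"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def make_daily(rows):
    """rows: (animal_id, iso date, weight[, n_records]) tuples."""
    rows = [r if len(r) == 4 else (*r, 1) for r in rows]
    df = pd.DataFrame(rows, columns=["animal_id", "date", "weight_kg", "n_records"])
    df["date"] = [datetime.date.fromisoformat(d) if isinstance(d, str) else d for d in df["date"]]
    return df


def make_references(rows):
    df = pd.DataFrame(rows, columns=["animal_id", "date", "weight_kg"])
    df["date"] = [datetime.date.fromisoformat(d) if isinstance(d, str) else d for d in df["date"]]
    return df
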