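import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from monarch_threats.datagen import DailyClimate, reduced_study_config, simulate_dataset

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def daily_climate():
    """Two sites in one region, three days each, plus one southern site."""
    days = pd.date_range("2001-06-01", periods=3)
    rows = []
    for site, offs in [("nc_a", 0.0), ("nc_b", 2.0)]:
        for d in days:
            rows.append(
                {"date": d, "site": site, "region": "north_central",
                 "tmax_c": 28.0 + offs, "tmin_c": 14.0}
            )
    for d in days:
        rows.append(
            {"date": d, "site": "s_a", "region": "south", "tmax_c": 33.0,
             "tmin_c": 20.0}
        )
    return DailyClimate(pd.DataFrame(rows))


@pytest.fixture
def small_dataset():
    """22-year dataset with 11 reduced-style covariates and known truth."""
    return simulate_dataset(reduced_study_config(seed=7))
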