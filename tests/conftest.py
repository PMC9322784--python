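import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stepvar.data import ActivitySeries

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

START = np.datetime64("2020-08-01")


def make_series(values, subject_id="S01", metric="steps", dates=None):
    values = np.asarray(values, dtype=float)
    if dates is None:
        dates = START + np.arange(len(values))
    else:
        dates = np.asarray(dates, dtype="datetime64[D]")
    return ActivitySeries(subject_id, metric, dates, values)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def default_cohort():
    from stepvar.simulate import SyntheticCohortConfig, simulate_cohort

    return simulate_cohort(SyntheticCohortConfig(seed=11))
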