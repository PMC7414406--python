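import datetime as dt

import pandas as pd
import pytest

from gravitrack import (CohortConfig, GestationalTimeline, process_cohort,
                        sample_cohort)


@pytest.fixture(scope="session")
def timeline():
    # delivery in gestational week 40 (day 275 = 7*39 + 2)
    return GestationalTimeline(
        conception_reference=dt.date(2023, 1, 2),
        delivery_date=dt.date(2023, 1, 2) + dt.timedelta(days=275))


@pytest.fixture(scope="session")
def tiny_config():
    return CohortConfig(n_participants=3, rng_seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return sample_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_processed(tiny_cohort):
    return process_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-condition cohort (20 participants, seed 1)."""
    return sample_cohort(CohortConfig(rng_seed=1))


@pytest.fixture(scope="session")
def default_processed(default_cohort):
    return process_cohort(default_cohort)


def minute_series(start: str, values, name="steps"):
    idx = pd.date_range(start, periods=len(values), freq="min")
    return pd.Series(values, index=idx, name=name)
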