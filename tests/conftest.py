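import datetime as dt
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

DATA = Path(__file__).parent / "data"

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=250,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def covered_days(spells) -> set:
    """Brute-force oracle: the set of covered calendar days, one by one."""
    days = set()
    for start, end in spells:
        d = start
        while d <= end:
            days.add(d)
            d += dt.timedelta(days=1)
    return days


@pytest.fixture(scope="session")
def golden_tables():
    persons = pd.read_csv(DATA / "golden_persons.csv")
    spells = pd.read_csv(
        DATA / "golden_spells.csv", parse_dates=["start_date", "end_date"]
    )
    cases = pd.read_csv(DATA / "golden_cases.csv", parse_dates=["admission_date"])
    cases["secondary_dx"] = cases["secondary_dx"].fillna("")
    return persons, spells, cases


@pytest.fixture(scope="session")
def golden_assignments(golden_tables):
    from washout import build_cohorts

    persons, spells, _ = golden_tables
    return build_cohorts(persons, spells, index_year=2017, lookbacks=(1, 3, 5))
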