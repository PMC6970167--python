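import pandas as pd
import pytest

from censusmort import build_standard
from censusmort.schema import DEATH_COLUMNS, PERSON_COLUMNS


@pytest.fixture(scope="session")
def standards():
    return build_standard()


@pytest.fixture(scope="session")
def male_std(standards):
    return standards["male"]


def make_persons(rows):
    """Build a persons frame from (household_id, is_head, age, sex, race,
    residence, region) tuples."""
    return pd.DataFrame(rows, columns=list(PERSON_COLUMNS))


def make_deaths(rows):
    """Build a deaths frame from (household_id, age_at_death, sex) tuples."""
    if not rows:
        return pd.DataFrame(
            {
                "household_id": pd.Series(dtype="int64"),
                "age_at_death": pd.Series(dtype="int64"),
                "sex": pd.Series(dtype="object"),
            }
        )
    return pd.DataFrame(rows, columns=list(DEATH_COLUMNS))


@pytest.fixture
def toy_microdata():
    """Three rural Indigenous households plus one urban white household."""
    persons = make_persons(
        [
            (0, True, 35, "male", "indigenous", "rural", "North"),
            (0, False, 0, "male", "indigenous", "rural", "North"),
            (0, False, 3, "male", "indigenous", "rural", "North"),
            (1, True, 40, "male", "indigenous", "rural", "North"),
            (1, False, 0, "male", "indigenous", "rural", "North"),
            (2, True, 50, "male", "indigenous", "rural", "North"),
            (2, False, 0, "male", "indigenous", "rural", "North"),
            (3, True, 28, "male", "white", "urban", "Northeast"),
            (3, False, 5, "male", "white", "urban", "Northeast"),
        ]
    )
    deaths = make_deaths([(0, 0, "male")])
    return persons, deaths
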