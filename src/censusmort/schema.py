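"""Shared categorical vocabulary and flat-file schemas.

The microdata mirror a census household survey: a persons table (one row per
enumerated resident) and a deaths table (household-reported deaths in the 12
months before the interview).  Deaths carry no color/race field — race is
attributed later from the head of household.
"""

from __future__ import annotations

import numpy as np

#: Census color/race categories.
RACES: tuple[str, ...] = ("white", "black", "brown", "yellow", "indigenous")

#: Race categories pooled into the non-Indigenous comparison group
#: ("yellow" is excluded from all analyses).
NON_INDIGENOUS_RACES: tuple[str, ...] = ("white", "black", "brown")

SEXES: tuple[str, ...] = ("male", "female")
RESIDENCES: tuple[str, ...] = ("urban", "rural")

#: The four analysis regions (South and Southeast are combined).
REGIONS4: tuple[str, ...] = ("North", "Northeast", "South/Southeast", "Central-West")

#: The five major census regions as collected.
REGIONS5: tuple[str, ...] = ("North", "Northeast", "South", "Southeast", "Central-West")

#: Study age range: completed years in the half-open interval [0, 20).
N_AGES: int = 20
AGES: np.ndarray = np.arange(N_AGES)

#: Reporting age groups (completed-year bounds, half-open).
AGE_GROUPS: dict[str, tuple[int, int]] = {
    "0-0.9": (0, 1),
    "1-4.9": (1, 5),
    "5-9.9": (5, 10),
    "10-19.9": (10, 20),
}

#: Column order of the persons file (UTF-8, comma-delimited, header row).
PERSON_COLUMNS: tuple[str, ...] = (
    "household_id",
    "is_head",
    "age",
    "sex",
    "race",
    "residence",
    "region",
)

#: Column order of the deaths file.  Note: no race column.
DEATH_COLUMNS: tuple[str, ...] = ("household_id", "age_at_death", "sex")
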