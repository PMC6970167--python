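"""Household Indigenous typologies and decedent race attribution.

Census deaths carry no color/race, so each decedent is attributed the
color/race of the head of their household.  Four household typologies
decide whether a household counts as Indigenous:

1. at least one Indigenous resident;
2. more than half of residents Indigenous (strict majority, head included);
3. all residents Indigenous;
4. head of household Indigenous (the pipeline default).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError
from .schema import NON_INDIGENOUS_RACES

logger = logging.getLogger(__name__)

__all__ = [
    "TYPOLOGIES",
    "build_household_index",
    "classify_household_typology",
    "household_indigenous_flags",
    "attribute_decedent_race",
    "assign_race_group",
    "compare_typologies",
]

TYPOLOGIES = (1, 2, 3, 4)


def build_household_index(persons: pd.DataFrame) -> pd.DataFrame:
    """Summarize households: head race, residence, region, size, Indigenous count.

    If a household has no ``is_head`` flag set, the oldest resident (first
    record on ties) is designated head; a warning is logged so imperfect
    data never breaks attribution.
    """
    if persons.empty:
        return pd.DataFrame(
            columns=["head_race", "residence", "region", "size", "n_indigenous"]
        )
    grouped = persons.groupby("household_id", sort=True)
    index = grouped.agg(
        residence=("residence", "first"),
        region=("region", "first"),
        size=("race", "size"),
        n_indigenous=("race", lambda r: int((r == "indigenous").sum())),
    )

    heads = persons[persons["is_head"]]
    n_heads = heads.groupby("household_id").size()
    multi = n_heads[n_heads > 1]
    if len(multi):
        raise DataIntegrityError(
            f"household(s) with more than one head: {list(multi.index[:5])}"
        )
    head_race = heads.set_index("household_id")["race"]

    headless = index.index.difference(head_race.index)
    if len(headless):
        logger.warning(
            "%d household(s) without a head flag; designating the oldest resident",
            len(headless),
        )
        fallback = (
            persons[persons["household_id"].isin(headless)]
            .sort_values(["household_id", "age"], ascending=[True, False], kind="stable")
            .groupby("household_id")["race"]
            .first()
        )
        head_race = pd.concat([head_race, fallback])

    index["head_race"] = head_race.reindex(index.index)
    return index[["head_race", "residence", "region", "size", "n_indigenous"]]


def classify_household_typology(
    resident_races: Sequence[str], head_race: str, typology: int
) -> bool:
    """Decide whether one household is Indigenous under a typology (1-4)."""
    if typology not in TYPOLOGIES:
        raise ConfigurationError(f"typology must be one of {TYPOLOGIES}, got {typology}")
    if len(resident_races) == 0:
        raise DataIntegrityError("household has no residents")
    n_ind = sum(r == "indigenous" for r in resident_races)
    size = len(resident_races)
    if typology == 1:
        return n_ind >= 1
    if typology == 2:
        return n_ind > size / 2  # strict majority; ties excluded
    if typology == 3:
        return n_ind == size
    return head_race == "indigenous"


def household_indigenous_flags(index: pd.DataFrame, typology: int) -> pd.Series:
    """Vectorized typology classification over a household index."""
    if typology not in TYPOLOGIES:
        raise ConfigurationError(f"typology must be one of {TYPOLOGIES}, got {typology}")
    if typology == 1:
        return index["n_indigenous"] >= 1
    if typology == 2:
        return index["n_indigenous"] > index["size"] / 2
    if typology == 3:
        return index["n_indigenous"] == index["size"]
    return index["head_race"] == "indigenous"


def attribute_decedent_race(deaths: pd.DataFrame, index: pd.DataFrame) -> pd.DataFrame:
    """Attach the head-of-household race (plus residence/region) to each death.

    Every death must resolve to a known household; unresolved household ids
    raise a :class:`DataIntegrityError` naming them.
    """
    if deaths.empty:
        out = deaths.copy()
        for col in ("attributed_race", "residence", "region"):
            out[col] = pd.Series(dtype="object")
        return out
    unknown = set(deaths["household_id"]) - set(index.index)
    if unknown:
        raise DataIntegrityError(
            f"death record(s) reference unknown household_id(s): {sorted(unknown)[:10]}"
        )
    out = deaths.merge(
        index[["head_race", "residence", "region"]],
        left_on="household_id",
        right_index=True,
        how="left",
    ).rename(columns={"head_race": "attributed_race"})
    return out.reset_index(drop=True)


def assign_race_group(
    persons: pd.DataFrame,
    deaths: pd.DataFrame,
    index: pd.DataFrame | None = None,
    typology: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label persons and deaths with attributed race and analysis race group.

    Adds ``attributed_race`` (the head's race) and ``race_group`` in
    {indigenous, non_indigenous, excluded}: a record is Indigenous when its
    household is Indigenous under the chosen typology; otherwise it is
    non-Indigenous when the head's race is white, black or brown, and
    excluded when the head's race is yellow.
    """
    if index is None:
        index = build_household_index(persons)
    flags = household_indigenous_flags(index, typology)

    def group_for(hh_ids: pd.Series, head_race: pd.Series) -> pd.Series:
        ind = flags.reindex(hh_ids).to_numpy()
        group = np.where(
            ind,
            "indigenous",
            np.where(head_race.isin(NON_INDIGENOUS_RACES), "non_indigenous", "excluded"),
        )
        return pd.Series(group, index=hh_ids.index)

    persons_out = persons.copy()
    persons_out["attributed_race"] = (
        index["head_race"].reindex(persons["household_id"]).to_numpy()
    )
    persons_out["race_group"] = group_for(
        persons["household_id"], persons_out["attributed_race"]
    ).to_numpy()

    deaths_out = attribute_decedent_race(deaths, index)
    if len(deaths_out):
        deaths_out["race_group"] = group_for(
            deaths_out["household_id"], deaths_out["attributed_race"]
        ).to_numpy()
    else:
        deaths_out["race_group"] = pd.Series(dtype="object")
    return persons_out, deaths_out


def compare_typologies(
    persons: pd.DataFrame,
    deaths: pd.DataFrame,
    config=None,
    typologies: Iterable[int] = TYPOLOGIES,
):
    """Run the full estimation pipeline once per typology.

    Returns a DataFrame of Indigenous age-group summaries stacked over
    typologies (column ``typology``), for side-by-side comparison.  The
    study this emulates found the four definitions gave similar estimates;
    no tolerance is asserted here — differences are simply reported.
    """
    from .lifetable import AnalysisConfig, run_full_analysis  # lazy: avoids cycle

    if config is None:
        config = AnalysisConfig()
    frames = []
    for typology in typologies:
        result = run_full_analysis(persons, deaths, replace_typology(config, typology))
        summary = result.summaries
        summary = summary[summary["stratum"] == "indigenous"].copy()
        summary.insert(0, "typology", typology)
        frames.append(summary)
    return pd.concat(frames, ignore_index=True)


def replace_typology(config, typology: int):
    from dataclasses import replace

    return replace(config, typology=typology)


def max_pairwise_infant_gap(comparison: pd.DataFrame) -> float:
    """Largest absolute per-1000 infant-q difference between any two typologies.

    Expects output of :func:`compare_typologies`; pools strata by summing
    nothing — the gap is taken within each (sex, residence, region) cell and
    the maximum over cells is returned.
    """
    infant = comparison[comparison["group"] == "0-0.9"]
    gaps = []
    for _, cell in infant.groupby(["sex", "residence", "region"], dropna=False):
        q = cell["q_per_1000"].to_numpy()
        if len(q) >= 2:
            gaps.append(float(q.max() - q.min()))
    return max(gaps) if gaps else 0.0
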