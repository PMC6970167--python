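"""Exposure/death tabulation by single year of age, with census exclusions.

Builds the D_x (deaths) and P_x (exposure, census headcount) vectors for
ages 0-19 per stratum of race group x sex x residence x region, excluding
the "yellow" category throughout and recombining the five major census
regions into four (South and Southeast pooled).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError
from .schema import AGES, N_AGES, NON_INDIGENOUS_RACES, REGIONS4, REGIONS5

__all__ = [
    "Stratum",
    "ExposureDeathTable",
    "recode_region",
    "tabulate",
    "composition_table",
    "composition_from_counts",
    "round_half_up",
    "write_exposure_tables",
]

_RACE_GROUPS = ("white", "black", "brown", "indigenous", "non_indigenous", "all")


@dataclass(frozen=True)
class Stratum:
    """A tabulation cell; the value ``"all"`` marginalizes a dimension."""

    race_group: str = "all"
    sex: str = "all"
    residence: str = "all"
    region: str = "all"

    def __post_init__(self) -> None:
        if self.race_group not in _RACE_GROUPS:
            raise ConfigurationError(
                f"race_group must be one of {_RACE_GROUPS}, got {self.race_group!r}"
            )

    def label(self) -> str:
        return ",".join(
            f"{k}={v}"
            for k, v in (
                ("race", self.race_group),
                ("sex", self.sex),
                ("residence", self.residence),
                ("region", self.region),
            )
            if v != "all"
        ) or "all"


@dataclass
class ExposureDeathTable:
    """Deaths D_x and exposures P_x for single ages 0-19 in one stratum."""

    stratum: Stratum
    exposure: np.ndarray
    deaths: np.ndarray

    def __post_init__(self) -> None:
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.deaths = np.asarray(self.deaths, dtype=float)
        if self.exposure.shape != (N_AGES,) or self.deaths.shape != (N_AGES,):
            raise ValueError(f"exposure and deaths must have length {N_AGES}")
        if np.any(self.exposure < 0) or np.any(self.deaths < 0):
            raise ValueError("exposure and deaths must be non-negative")

    def __add__(self, other: "ExposureDeathTable") -> "ExposureDeathTable":
        return ExposureDeathTable(
            stratum=self.stratum,
            exposure=self.exposure + other.exposure,
            deaths=self.deaths + other.deaths,
        )

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())

    @property
    def total_exposure(self) -> float:
        return float(self.exposure.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum.label(),
                "age": AGES,
                "exposure": self.exposure,
                "deaths": self.deaths,
            }
        )


def recode_region(region_5: str) -> str:
    """Map the five major census regions onto the four analysis regions."""
    if region_5 in ("South", "Southeast", "South/Southeast"):
        return "South/Southeast"
    if region_5 in REGIONS4:
        return region_5
    raise ConfigurationError(
        f"unknown region {region_5!r}; expected one of {REGIONS5 + ('South/Southeast',)}"
    )


def _match(frame: pd.DataFrame, stratum: Stratum, age_col: str) -> pd.Series:
    mask = frame[age_col].between(0, N_AGES - 1)
    if stratum.race_group in ("indigenous", "non_indigenous"):
        mask &= frame["race_group"] == stratum.race_group
    elif stratum.race_group in NON_INDIGENOUS_RACES:
        mask &= frame["attributed_race"] == stratum.race_group
    else:  # "all": everything except the excluded (yellow-headed) records
        mask &= frame["race_group"] != "excluded"
    if stratum.sex != "all":
        mask &= frame["sex"] == stratum.sex
    if stratum.residence != "all":
        mask &= frame["residence"] == stratum.residence
    if stratum.region != "all":
        mask &= frame["region"].map(recode_region) == stratum.region
    return mask


def tabulate(
    persons: pd.DataFrame,
    attributed_deaths: pd.DataFrame,
    stratum: Stratum,
    exposure_correction: bool = False,
) -> ExposureDeathTable:
    """Count exposures and attributed deaths by single year of age.

    ``persons`` and ``attributed_deaths`` must carry the ``attributed_race``
    and ``race_group`` columns produced by
    :func:`censusmort.attribution.assign_race_group`.  Exposure is the
    census headcount at interview; with ``exposure_correction`` half a
    person-year per death is added back (decedents not enumerated).
    """
    for frame, name in ((persons, "persons"), (attributed_deaths, "deaths")):
        missing = {"attributed_race", "race_group"} - set(frame.columns)
        if missing and not frame.empty:
            raise DataIntegrityError(
                f"{name} table lacks column(s) {sorted(missing)}; "
                "run attribution.assign_race_group first"
            )
    p_sel = persons[_match(persons, stratum, "age")] if len(persons) else persons
    exposure = np.zeros(N_AGES)
    if len(p_sel):
        counts = p_sel.groupby("age").size()
        exposure[counts.index.to_numpy()] = counts.to_numpy()

    deaths = np.zeros(N_AGES)
    if len(attributed_deaths):
        d_sel = attributed_deaths[_match(attributed_deaths, stratum, "age_at_death")]
        if len(d_sel):
            counts = d_sel.groupby("age_at_death").size()
            deaths[counts.index.to_numpy()] = counts.to_numpy()

    if exposure_correction:
        exposure = exposure + deaths / 2.0
    return ExposureDeathTable(stratum=stratum, exposure=exposure, deaths=deaths)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed census tables).

    Uses decimal arithmetic on the shortest repr so values like 83.85 round
    up to 83.9 despite binary floating-point representation.
    """
    import decimal

    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(float(x))).quantize(
            quantum, rounding=decimal.ROUND_HALF_UP
        )
    )


def composition_from_counts(counts: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Region x rural/urban composition table from raw counts.

    ``counts`` maps region -> (rural_n, urban_n).  Returns one row per
    region plus a Total row, with row percentages rounded half-up to one
    decimal.
    """
    rows = []
    for region, (rural_n, urban_n) in counts.items():
        total = rural_n + urban_n
        rows.append(
            {
                "region": region,
                "rural_n": rural_n,
                "rural_pct": round_half_up(100.0 * rural_n / total) if total else 0.0,
                "urban_n": urban_n,
                "urban_pct": round_half_up(100.0 * urban_n / total) if total else 0.0,
                "total_n": total,
            }
        )
    rural_all = sum(r["rural_n"] for r in rows)
    urban_all = sum(r["urban_n"] for r in rows)
    grand = rural_all + urban_all
    rows.append(
        {
            "region": "Total",
            "rural_n": rural_all,
            "rural_pct": round_half_up(100.0 * rural_all / grand) if grand else 0.0,
            "urban_n": urban_all,
            "urban_pct": round_half_up(100.0 * urban_all / grand) if grand else 0.0,
            "total_n": grand,
        }
    )
    return pd.DataFrame(rows)


def composition_table(persons: pd.DataFrame) -> pd.DataFrame:
    """Composition of the self-declared Indigenous population aged <20.

    Counts by analysis region x rural/urban residence with row percentages,
    matching the layout of the census composition table.
    """
    study = persons[(persons["race"] == "indigenous") & (persons["age"] < N_AGES)]
    counts = {}
    for region in REGIONS4:
        in_region = study[study["region"].map(recode_region) == region] if len(study) else study
        counts[region] = (
            float((in_region["residence"] == "rural").sum()),
            float((in_region["residence"] == "urban").sum()),
        )
    return composition_from_counts(counts)


def write_exposure_tables(
    tables: Iterable[ExposureDeathTable], path: str | Path
) -> Path:
    """Export tables as delimited text: stratum,age,exposure,deaths."""
    path = Path(path)
    frame = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    frame.to_csv(path, index=False)
    return path
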