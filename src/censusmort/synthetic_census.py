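"""Synthetic census microdata with known true mortality schedules.

Emulates the design of a household census that asks every household about
deaths of residents in the previous 12 months: a persons table enumerates
residents (with color/race declared for everyone), while the deaths table
records only the decedent's age and sex — never race, which must later be
attributed from the head of household.

Households are built around a head whose race is drawn from a stratum race
mix; other members share the head's race with probability ``homogeneity``
and are otherwise redrawn from the mix, giving a single dial for
within-household racial homogeneity.  Deaths are drawn per person as
Bernoulli with p = 1 - exp(-m) from stratum- and race-specific true
schedules, so every downstream estimate can be checked against known truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .schema import (
    DEATH_COLUMNS,
    N_AGES,
    PERSON_COLUMNS,
    RACES,
    REGIONS4,
    RESIDENCES,
    SEXES,
)
from .standard import StandardSchedule, build_standard

logger = logging.getLogger(__name__)

__all__ = [
    "StratumSpec",
    "SimulationConfig",
    "generate_population",
    "generate_deaths",
    "apply_single_person_censoring",
    "write_microdata",
    "read_microdata",
    "example_config",
    "simulate",
]

# Fixed per-stage offsets so each stage draws from its own reproducible
# sub-stream of the run seed.
_POPULATION_STREAM = 11
_DEATH_STREAM = 23

_PROB_TOL = 1e-9


def _stage_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


@dataclass(frozen=True)
class StratumSpec:
    """One simulated stratum: sex x residence x region with its own race mix."""

    sex: str
    residence: str
    region: str
    race_mix: Mapping[str, float]
    n_households: int

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if self.residence not in RESIDENCES:
            raise ConfigurationError(f"unknown residence {self.residence!r}")
        if self.region not in REGIONS4:
            raise ConfigurationError(f"unknown region {self.region!r}")
        if self.n_households < 0:
            raise ConfigurationError("n_households must be non-negative")
        unknown = set(self.race_mix) - set(RACES)
        if unknown:
            raise ConfigurationError(f"unknown race(s) in race_mix: {sorted(unknown)}")
        probs = np.array(list(self.race_mix.values()), dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ConfigurationError(
                f"race_mix for stratum ({self.sex},{self.residence},{self.region}) "
                f"must be non-negative and sum to 1 (got sum {probs.sum():.12f})"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Full simulation scenario.

    Parameters
    ----------
    strata
        Stratum specifications (sex, residence, region, race mix, size).
    household_size_probs
        Probabilities over household sizes 1..len(probs) (max 10).
    homogeneity
        Probability that a non-head member shares the head's race.
    true_schedules
        Map (sex, residence, region, race) -> length-20 array of true
        single-year central death rates for ages 0-19.
    censor_single_person_deaths
        If True, deaths in single-person households erase the household
        (it no longer exists at interview time, so it is not enumerated).
    age_sampler
        Optional hook ``(rng, n) -> int array`` for non-head ages;
        default uniform on 0-19.
    """

    strata: Sequence[StratumSpec]
    household_size_probs: Sequence[float] = (0.12, 0.22, 0.26, 0.22, 0.12, 0.06)
    homogeneity: float = 0.9
    true_schedules: Mapping[tuple[str, str, str, str], np.ndarray] = field(
        default_factory=dict
    )
    censor_single_person_deaths: bool = False
    seed: int = 0
    age_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None

    def validate(self) -> None:
        for spec in self.strata:
            spec.validate()
        probs = np.asarray(self.household_size_probs, dtype=float)
        if probs.ndim != 1 or len(probs) < 1 or len(probs) > 10:
            raise ConfigurationError("household_size_probs must cover sizes 1..10")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ConfigurationError("household_size_probs must sum to 1")
        if not 0.0 <= self.homogeneity <= 1.0:
            raise ConfigurationError("homogeneity must lie in [0, 1]")
        for key, rates in self.true_schedules.items():
            rates = np.asarray(rates, dtype=float)
            if rates.shape != (N_AGES,) or np.any(rates < 0):
                raise ConfigurationError(
                    f"true schedule for {key} must be 20 non-negative rates"
                )

    def schedule_for(self, sex: str, residence: str, region: str, race: str) -> np.ndarray:
        key = (sex, residence, region, race)
        try:
            return np.asarray(self.true_schedules[key], dtype=float)
        except KeyError:
            raise ConfigurationError(
                f"no true mortality schedule for stratum x race {key}"
            ) from None


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Generate the persons table for all strata of a scenario.

    Each household has exactly one head (age 20-80, never in the 0-19 study
    population); non-head members get ages 0-19 (uniform unless an
    ``age_sampler`` hook is supplied) and share the head's race with
    probability ``homogeneity``.  Deterministic under a fixed seed.
    """
    config.validate()
    rng = _stage_rng(config.seed, _POPULATION_STREAM)
    sizes_support = np.arange(1, len(config.household_size_probs) + 1)

    frames: list[pd.DataFrame] = []
    next_household = 0
    for spec in config.strata:
        n_hh = spec.n_households
        if n_hh == 0:
            continue
        races = np.array(list(spec.race_mix.keys()))
        mix = np.array(list(spec.race_mix.values()), dtype=float)
        mix = mix / mix.sum()

        sizes = rng.choice(sizes_support, size=n_hh, p=config.household_size_probs)
        hh_ids = np.arange(next_household, next_household + n_hh)
        next_household += n_hh

        head_race = rng.choice(races, size=n_hh, p=mix)
        head_age = rng.integers(20, 81, size=n_hh)

        n_members = sizes - 1
        member_hh = np.repeat(hh_ids, n_members)
        member_race = np.repeat(head_race, n_members)
        redraw = rng.random(member_hh.size) >= config.homogeneity
        if redraw.any():
            member_race = member_race.copy()
            member_race[redraw] = rng.choice(races, size=int(redraw.sum()), p=mix)
        if config.age_sampler is not None:
            member_age = np.asarray(config.age_sampler(rng, member_hh.size), dtype=int)
            if member_age.shape != member_hh.shape or np.any(member_age < 0):
                raise ConfigurationError("age_sampler must return non-negative ages, one per member")
        else:
            member_age = rng.integers(0, N_AGES, size=member_hh.size)

        frame = pd.DataFrame(
            {
                "household_id": np.concatenate([hh_ids, member_hh]),
                "is_head": np.concatenate(
                    [np.ones(n_hh, dtype=bool), np.zeros(member_hh.size, dtype=bool)]
                ),
                "age": np.concatenate([head_age, member_age]),
                "sex": spec.sex,
                "race": np.concatenate([head_race, member_race]),
                "residence": spec.residence,
                "region": spec.region,
            }
        )
        frames.append(frame)

    if not frames:
        persons = pd.DataFrame(
            {col: pd.Series(dtype=t) for col, t in _PERSON_DTYPES.items()}
        )
    else:
        persons = pd.concat(frames, ignore_index=True)
        persons = persons.sort_values(
            ["household_id", "is_head"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    logger.info("generate_population: %d persons in %d households", len(persons), next_household)
    return persons[list(PERSON_COLUMNS)]


_PERSON_DTYPES = {
    "household_id": "int64",
    "is_head": "bool",
    "age": "int64",
    "sex": "object",
    "race": "object",
    "residence": "object",
    "region": "object",
}


def generate_deaths(persons: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Draw household-reported deaths from the true schedules.

    Each person aged 0-19 dies within the reference year with probability
    1 - exp(-m_true(x)).  The death record carries the household, age and
    sex but no race; the person stays in the persons table (the census
    enumerates the household after the death and the death is reported
    retrospectively).  Deterministic under a fixed seed.
    """
    config.validate()
    rng = _stage_rng(config.seed, _DEATH_STREAM)
    study = persons[persons["age"] < N_AGES]
    if study.empty:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _DEATH_DTYPES.items()})

    hazard = np.empty(len(study), dtype=float)
    groups = study.groupby(["sex", "residence", "region", "race"], sort=True)
    for key, idx in groups.indices.items():
        rates = config.schedule_for(*key)
        hazard[idx] = rates[study["age"].to_numpy()[idx]]

    p_death = -np.expm1(-hazard)
    died = rng.random(len(study)) < p_death
    deaths = pd.DataFrame(
        {
            "household_id": study["household_id"].to_numpy()[died],
            "age_at_death": study["age"].to_numpy()[died],
            "sex": study["sex"].to_numpy()[died],
        }
    )
    logger.info("generate_deaths: %d deaths among %d persons at risk", len(deaths), len(study))
    return deaths[list(DEATH_COLUMNS)]


_DEATH_DTYPES = {"household_id": "int64", "age_at_death": "int64", "sex": "object"}


def apply_single_person_censoring(
    persons: pd.DataFrame, deaths: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove deaths (and their households) in single-person households.

    A one-person household whose resident died no longer exists at
    interview time, so neither the household nor its death report is
    observed.  Households of size >= 2 are untouched.
    """
    sizes = persons.groupby("household_id").size()
    single = set(sizes[sizes == 1].index)
    censored_hh = set(deaths["household_id"]) & single
    if not censored_hh:
        return persons.copy(), deaths.copy()
    persons_out = persons[~persons["household_id"].isin(censored_hh)].reset_index(drop=True)
    deaths_out = deaths[~deaths["household_id"].isin(censored_hh)].reset_index(drop=True)
    logger.info(
        "apply_single_person_censoring: removed %d household(s) and %d death(s)",
        len(censored_hh),
        len(deaths) - len(deaths_out),
    )
    return persons_out, deaths_out


def write_microdata(
    persons: pd.DataFrame, deaths: pd.DataFrame, path_prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>_persons.csv`` and ``<prefix>_deaths.csv``."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    persons_path = prefix.with_name(prefix.name + "_persons.csv")
    deaths_path = prefix.with_name(prefix.name + "_deaths.csv")
    persons[list(PERSON_COLUMNS)].to_csv(persons_path, index=False)
    deaths[list(DEATH_COLUMNS)].to_csv(deaths_path, index=False)
    return persons_path, deaths_path


def read_microdata(path_prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read microdata written by :func:`write_microdata`."""
    prefix = Path(path_prefix)
    persons_path = prefix.with_name(prefix.name + "_persons.csv")
    deaths_path = prefix.with_name(prefix.name + "_deaths.csv")
    for p in (persons_path, deaths_path):
        if not p.exists():
            raise ConfigurationError(f"microdata file not found: {p}")
    persons = pd.read_csv(persons_path, dtype=_PERSON_DTYPES)
    deaths = pd.read_csv(deaths_path, dtype=_DEATH_DTYPES)
    return persons[list(PERSON_COLUMNS)], deaths[list(DEATH_COLUMNS)]


# ---------------------------------------------------------------------------
# Bundled example scenario
# ---------------------------------------------------------------------------

# Indigenous population <20 by region x residence in the 2010 census frame
# (persons); the example scenario scales Indigenous household shares so the
# simulated regional rural/urban composition tracks these proportions
# (overall rural share ~74%).
_COMPOSITION_2010: dict[tuple[str, str], int] = {
    ("North", "rural"): 141_015,
    ("North", "urban"): 27_092,
    ("Northeast", "rural"): 51_613,
    ("Northeast", "urban"): 33_910,
    ("South/Southeast", "rural"): 31_675,
    ("South/Southeast", "urban"): 26_527,
    ("Central-West", "rural"): 56_367,
    ("Central-West", "urban"): 10_163,
}

# Non-Indigenous race shares in the 2010 census (white/black/brown/yellow),
# renormalized within each stratum's non-Indigenous remainder.
_NON_INDIGENOUS_MIX = {"white": 0.477, "black": 0.076, "brown": 0.431, "yellow": 0.011}


def example_config(
    seed: int = 0,
    n_households: int = 2000,
    indigenous_rate_ratio: float = 2.0,
    rural_rate_ratio: float = 1.3,
    homogeneity: float = 0.9,
    censor_single_person_deaths: bool = False,
    standards: dict[str, StandardSchedule] | None = None,
) -> SimulationConfig:
    """Build a ready-to-run scenario over all region/residence/sex strata.

    True non-Indigenous rates equal the (sex-specific) standard schedule,
    scaled by ``rural_rate_ratio`` in rural strata; Indigenous rates are
    ``indigenous_rate_ratio`` times the non-Indigenous rates of the same
    stratum.  Indigenous household shares vary by region and residence so
    the simulated Indigenous composition tracks the census pattern of a
    predominantly rural Indigenous population.
    """
    if standards is None:
        standards = build_standard()
    max_count = max(_COMPOSITION_2010.values())

    strata: list[StratumSpec] = []
    schedules: dict[tuple[str, str, str, str], np.ndarray] = {}
    for region in REGIONS4:
        for residence in RESIDENCES:
            p_ind = 0.4 * _COMPOSITION_2010[(region, residence)] / max_count
            remainder = 1.0 - p_ind
            nic_total = sum(_NON_INDIGENOUS_MIX.values())
            mix = {
                race: remainder * share / nic_total
                for race, share in _NON_INDIGENOUS_MIX.items()
            }
            mix["indigenous"] = p_ind
            for sex in SEXES:
                strata.append(
                    StratumSpec(
                        sex=sex,
                        residence=residence,
                        region=region,
                        race_mix=mix,
                        n_households=n_households,
                    )
                )
                base = standards[sex].rates * (
                    rural_rate_ratio if residence == "rural" else 1.0
                )
                for race in RACES:
                    ratio = indigenous_rate_ratio if race == "indigenous" else 1.0
                    schedules[(sex, residence, region, race)] = base * ratio
    return SimulationConfig(
        strata=strata,
        homogeneity=homogeneity,
        true_schedules=schedules,
        censor_single_person_deaths=censor_single_person_deaths,
        seed=seed,
    )


def simulate(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full generator: population, deaths, optional censoring."""
    persons = generate_population(config)
    deaths = generate_deaths(persons, config)
    if config.censor_single_person_deaths:
        persons, deaths = apply_single_person_censoring(persons, deaths)
    return persons, deaths
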