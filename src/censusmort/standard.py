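"""Standard mortality schedules for the relational (TOPALS) fit.

TOPALS estimates a population's log mortality schedule as a *standard*
schedule plus a linear-spline offset, so the core input here is a vector of
single-year log death rates for ages 0-19, by sex.  Because the official
national life table is an external product, the bundled default standard is
generated from a Siler hazard — a three-component parametric model
(declining childhood risk + constant background + rising senescent risk)
whose shape over ages 0-19 is a good stand-in for a national 2010-era
schedule.  Any user-supplied single-year life table (columns ``age,mx``)
can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataIntegrityError
from .schema import AGES, N_AGES

__all__ = [
    "SilerParams",
    "StandardSchedule",
    "siler_hazard",
    "build_standard",
    "read_life_table",
    "write_life_table",
    "DEFAULT_SILER_PARAMS",
]


@dataclass(frozen=True)
class SilerParams:
    """Siler hazard parameters: h(x) = a1*exp(-b1*x) + a2 + a3*exp(b3*x)."""

    a1: float
    b1: float
    a2: float
    a3: float
    b3: float

    def __post_init__(self) -> None:
        for name in ("a1", "b1", "a2", "a3", "b3"):
            if getattr(self, name) < 0:
                raise ValueError(f"Siler parameter {name} must be non-negative")
        if np.any(siler_hazard(self, AGES) <= 0):
            raise ValueError("Siler hazard must be strictly positive on ages 0-19")


def siler_hazard(params: SilerParams, age):
    """Evaluate the Siler hazard at one or more (non-negative) ages."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    h = (
        params.a1 * np.exp(-params.b1 * age)
        + params.a2
        + params.a3 * np.exp(params.b3 * age)
    )
    return h if h.ndim else float(h)


@dataclass(frozen=True)
class StandardSchedule:
    """Single-year log central death rates for ages 0-19, one sex."""

    sex: str
    log_rates: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        log_rates = np.asarray(self.log_rates, dtype=float)
        if log_rates.shape != (N_AGES,):
            raise ValueError(f"log_rates must have length {N_AGES}")
        if not np.all(np.isfinite(log_rates)):
            raise ValueError("log_rates must be finite (rates strictly positive)")
        object.__setattr__(self, "log_rates", log_rates)

    @property
    def rates(self) -> np.ndarray:
        """Central death rates m_x (per person-year)."""
        return np.exp(self.log_rates)


# Fixture parameters shaped like a national 2010-era schedule: infant rate
# near 0.016 (male) / 0.013 (female), a deep childhood trough, and a rise
# through adolescence reaching ~0.0016 for males at 19 (external-cause
# mortality is far higher for young men).
DEFAULT_SILER_PARAMS: dict[str, SilerParams] = {
    "male": SilerParams(a1=0.01578, b1=1.8, a2=2.0e-4, a3=1.2e-5, b3=0.25),
    "female": SilerParams(a1=0.0131, b1=1.9, a2=1.5e-4, a3=5.0e-6, b3=0.26),
}


def build_standard(
    params_by_sex: dict[str, SilerParams] | None = None,
) -> dict[str, StandardSchedule]:
    """Build sex-specific standard schedules from Siler parameters.

    With no argument, returns the bundled default standards.
    """
    if params_by_sex is None:
        params_by_sex = DEFAULT_SILER_PARAMS
    return {
        sex: StandardSchedule(sex=sex, log_rates=np.log(siler_hazard(p, AGES)))
        for sex, p in params_by_sex.items()
    }


def read_life_table(path: str | Path, sex: str = "all") -> StandardSchedule:
    """Read a single-year life-table file (columns ``age,mx``, ages 0-19).

    Raises
    ------
    DataIntegrityError
        If ages are missing/duplicated or any mx is non-positive; the message
        names the offending rows.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing_cols = {"age", "mx"} - set(table.columns)
    if missing_cols:
        raise DataIntegrityError(
            f"{path}: missing required column(s) {sorted(missing_cols)}"
        )
    ages_present = set(table["age"].astype(int))
    missing_ages = sorted(set(range(N_AGES)) - ages_present)
    if missing_ages:
        raise DataIntegrityError(f"{path}: missing age(s) {missing_ages}")
    if table["age"].duplicated().any():
        dupes = sorted(table.loc[table["age"].duplicated(), "age"].astype(int))
        raise DataIntegrityError(f"{path}: duplicated age(s) {dupes}")
    bad = table[table["mx"] <= 0]
    if not bad.empty:
        raise DataIntegrityError(
            f"{path}: non-positive mx at age(s) {sorted(bad['age'].astype(int))} "
            "(log rate undefined)"
        )
    table = table.set_index(table["age"].astype(int)).sort_index()
    mx = table.loc[list(range(N_AGES)), "mx"].to_numpy(dtype=float)
    return StandardSchedule(sex=sex, log_rates=np.log(mx))


def write_life_table(schedule: StandardSchedule, path: str | Path) -> Path:
    """Write a schedule as an ``age,mx`` file (round-trips with the reader)."""
    path = Path(path)
    frame = pd.DataFrame({"age": AGES, "mx": schedule.rates})
    frame.to_csv(path, index=False, float_format="%.15g")
    return path
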