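"""Age-group probabilities of dying and stratified group comparisons.

Fitted single-year central death rates m_x are converted to the reporting
quantity: the probability q_g that a person alive at the start of age group
g dies before its end, assuming a constant hazard within each single year:

    q_g = 1 - exp(-sum_{x in g} m_x),

reported per 1000 with 95% intervals obtained by pushing multivariate
normal draws of the spline offsets through the rate-to-probability map.
The reporting groups are 0-0.9, 1-4.9, 5-9.9 and 10-19.9 years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import attribution, tabulation
from .errors import ConfigurationError, NumericalError
from .schema import AGE_GROUPS, REGIONS4, RESIDENCES, SEXES
from .standard import StandardSchedule, build_standard
from .tabulation import Stratum
from .topals import TopalsFit, TopalsSpec, build_basis, fit_topals

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "AnalysisResult",
    "group_q_from_rates",
    "group_q_ci",
    "summarize_fit",
    "compare_strata",
    "run_full_analysis",
]


def _group_bounds(group) -> tuple[int, int]:
    if isinstance(group, str):
        try:
            return AGE_GROUPS[group]
        except KeyError:
            raise ConfigurationError(
                f"unknown age group {group!r}; expected one of {list(AGE_GROUPS)}"
            ) from None
    lo, hi = group
    return int(lo), int(hi)


def group_q_from_rates(
    rates, group, infant_separation: bool = False, a0: float = 0.1
) -> float:
    """Probability of dying across an age group from single-year rates.

    Constant hazard within each completed year gives
    q = 1 - exp(-sum m_x).  For the infant group the optional separation
    factor a0 switches to the classical conversion
    q0 = m0 / (1 + (1 - a0) m0), which weights deaths toward the start of
    the first year of life.
    """
    lo, hi = _group_bounds(group)
    rates = np.asarray(rates, dtype=float)
    if rates.shape[0] < hi:
        raise ConfigurationError(f"rates must cover ages up to {hi - 1}")
    chunk = rates[lo:hi]
    if np.any(~np.isfinite(chunk)) or np.any(chunk < 0):
        raise ConfigurationError("rates must be finite and non-negative")
    if infant_separation and (lo, hi) == (0, 1):
        m0 = float(chunk[0])
        return m0 / (1.0 + (1.0 - a0) * m0)
    return float(-np.expm1(-chunk.sum()))


def group_q_ci(
    fit: TopalsFit,
    group,
    n_draws: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    infant_separation: bool = False,
) -> tuple[float, float]:
    """Simulation interval for q_g: normal draws of alpha pushed through rates.

    q is a nonlinear functional of several rates, so rather than a delta
    method the interval comes from ``n_draws`` seeded multivariate-normal
    draws of the offsets at (alpha-hat, Cov), each mapped to rates and
    then to q_g; bounds are the (1-level)/2 tail percentiles.
    """
    eigvals = np.linalg.eigvalsh(fit.covariance)
    if eigvals.min() < -1e-8 * max(1.0, abs(eigvals.max())):
        raise NumericalError("offset covariance is not positive semidefinite")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        fit.alpha, fit.covariance, size=n_draws, method="svd"
    )
    B = build_basis(fit.spec.knots)
    log_rates = fit.std_log_rates + draws @ B.T
    qs = np.array(
        [
            group_q_from_rates(np.exp(lr), group, infant_separation=infant_separation)
            for lr in log_rates
        ]
    )
    tail = 100.0 * (1.0 - level) / 2.0
    return float(np.percentile(qs, tail)), float(np.percentile(qs, 100.0 - tail))


def summarize_fit(
    fit: TopalsFit,
    n_draws: int = 1000,
    seed: int | None = None,
    infant_separation: bool = False,
) -> pd.DataFrame:
    """Per-1000 probabilities of dying with 95% intervals for all age groups."""
    rows = []
    for group in AGE_GROUPS:
        q = group_q_from_rates(fit.fitted_rates, group, infant_separation)
        lo, hi = group_q_ci(
            fit, group, n_draws=n_draws, seed=seed, infant_separation=infant_separation
        )
        rows.append(
            {
                "group": group,
                "q": q,
                "q_per_1000": round(1000.0 * q, 1),
                "lower95": round(1000.0 * lo, 1),
                "upper95": round(1000.0 * hi, 1),
            }
        )
    return pd.DataFrame(rows)


def compare_strata(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame, label_a: str = "A", label_b: str = "B"
) -> pd.DataFrame:
    """Per-group ratio of probabilities (A/B) and CI-overlap flag."""
    if list(summary_a["group"]) != list(summary_b["group"]):
        raise ConfigurationError("summaries cover different age groups")
    rows = []
    for (_, a), (_, b) in zip(summary_a.iterrows(), summary_b.iterrows()):
        overlap = (a["lower95"] <= b["upper95"]) and (b["lower95"] <= a["upper95"])
        rows.append(
            {
                "group": a["group"],
                f"{label_a}_per_1000": a["q_per_1000"],
                f"{label_a}_lower95": a["lower95"],
                f"{label_a}_upper95": a["upper95"],
                f"{label_b}_per_1000": b["q_per_1000"],
                f"{label_b}_lower95": b["lower95"],
                f"{label_b}_upper95": b["upper95"],
                "ratio": round(a["q"] / b["q"], 2) if b["q"] > 0 else np.inf,
                "ci_overlap": bool(overlap),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnalysisConfig:
    """End-to-end analysis settings."""

    standards: Mapping[str, StandardSchedule] = field(default_factory=build_standard)
    typology: int = 4
    topals: TopalsSpec = field(default_factory=TopalsSpec)
    by_sex: bool = True
    by_residence: bool = True
    by_region: bool = False
    exposure_correction: bool = False
    infant_separation: bool = False
    n_draws: int = 1000
    seed: int = 0


@dataclass
class AnalysisResult:
    """Everything the pipeline produces for one run."""

    composition: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    fits: dict[tuple, TopalsFit]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "composition": outdir / "composition.csv",
            "summaries": outdir / "summaries.csv",
            "comparisons": outdir / "comparisons.csv",
        }
        self.composition.to_csv(paths["composition"], index=False)
        self.summaries.to_csv(paths["summaries"], index=False)
        self.comparisons.to_csv(paths["comparisons"], index=False)
        return paths


def run_full_analysis(
    persons: pd.DataFrame, deaths: pd.DataFrame, config: AnalysisConfig | None = None
) -> AnalysisResult:
    """Attribution -> tabulation -> TOPALS -> age-group summaries.

    Fits Indigenous and non-Indigenous strata crossed with sex, residence
    and (optionally) region, then compares the two groups within every
    cell.  Strata with zero exposure at every age are skipped with a
    warning.  All randomness (interval draws) derives from ``config.seed``.
    """
    config = config or AnalysisConfig()
    index = attribution.build_household_index(persons)
    persons_g, deaths_g = attribution.assign_race_group(
        persons, deaths, index, typology=config.typology
    )
    logger.info(
        "attribution: %d persons, %d deaths, typology %d",
        len(persons_g),
        len(deaths_g),
        config.typology,
    )
    composition = tabulation.composition_table(persons)

    sexes: Sequence[str] = SEXES if config.by_sex else ("all",)
    residences: Sequence[str] = RESIDENCES if config.by_residence else ("all",)
    regions: Sequence[str] = REGIONS4 if config.by_region else ("all",)

    fits: dict[tuple, TopalsFit] = {}
    summary_rows = []
    cell_counter = 0
    for sex in sexes:
        if sex == "all":
            if "all" not in config.standards:
                raise ConfigurationError(
                    "by_sex=False requires a standard schedule keyed 'all'"
                )
            standard = config.standards["all"]
        else:
            standard = config.standards[sex]
        for residence in residences:
            for region in regions:
                for race_group in ("indigenous", "non_indigenous"):
                    stratum = Stratum(race_group, sex, residence, region)
                    table = tabulation.tabulate(
                        persons_g,
                        deaths_g,
                        stratum,
                        exposure_correction=config.exposure_correction,
                    )
                    if table.total_exposure == 0:
                        logger.warning("stratum %s has no exposure; skipped", stratum.label())
                        continue
                    if table.total_deaths == 0:
                        # with zero deaths the level offset is unbounded below
                        # (the likelihood has no maximum); the stratum is not
                        # identifiable and is skipped
                        logger.warning("stratum %s has no deaths; skipped", stratum.label())
                        continue
                    fit = fit_topals(
                        table.deaths,
                        table.exposure,
                        standard,
                        config.topals,
                        stratum=stratum.label(),
                    )
                    cell_counter += 1
                    summary = summarize_fit(
                        fit,
                        n_draws=config.n_draws,
                        seed=(config.seed + cell_counter) % (2**31),
                        infant_separation=config.infant_separation,
                    )
                    fits[(race_group, sex, residence, region)] = fit
                    for _, row in summary.iterrows():
                        summary_rows.append(
                            {
                                "stratum": race_group,
                                "sex": sex,
                                "residence": residence,
                                "region": region,
                                **row.to_dict(),
                            }
                        )
                    logger.info(
                        "fit %s: %.0f deaths / %.0f exposure, converged=%s",
                        stratum.label(),
                        table.total_deaths,
                        table.total_exposure,
                        fit.converged,
                    )

    summaries = pd.DataFrame(summary_rows)

    comparison_rows = []
    for sex in sexes:
        for residence in residences:
            for region in regions:
                key_i = ("indigenous", sex, residence, region)
                key_n = ("non_indigenous", sex, residence, region)
                if key_i not in fits or key_n not in fits:
                    continue
                sub = summaries[
                    (summaries["sex"] == sex)
                    & (summaries["residence"] == residence)
                    & (summaries["region"] == region)
                ]
                comp = compare_strata(
                    sub[sub["stratum"] == "indigenous"].reset_index(drop=True),
                    sub[sub["stratum"] == "non_indigenous"].reset_index(drop=True),
                    label_a="indigenous",
                    label_b="non_indigenous",
                )
                comp.insert(1, "sex", sex)
                comp.insert(2, "residence", residence)
                comp.insert(3, "region", region)
                comparison_rows.append(comp)
    comparisons = (
        pd.concat(comparison_rows, ignore_index=True)
        if comparison_rows
        else pd.DataFrame()
    )
    logger.info(
        "run_full_analysis: %d strata fitted, %d comparison cells",
        len(fits),
        sum(len(c) for c in comparison_rows) // max(len(AGE_GROUPS), 1),
    )
    return AnalysisResult(
        composition=composition, summaries=summaries, comparisons=comparisons, fits=fits
    )
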