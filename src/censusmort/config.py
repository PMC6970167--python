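"""Flat-file run configuration shared by the CLI subcommands.

A run is a pure function of (config, seed): the config file is a flat YAML
mapping whose keys mirror the command-line flags 1:1; flags override file
values; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .topals import DEFAULT_KNOTS

__all__ = ["RunConfig", "parse_config"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs for a reproducible pipeline run."""

    # paths
    persons: str | None = None
    deaths: str | None = None
    standard: str | None = None  # age,mx file; None -> bundled Siler standard
    out: str = "results"
    # attribution / tabulation
    typology: int = 4
    exposure_correction: bool = False
    # TOPALS
    knots: tuple[int, ...] = DEFAULT_KNOTS
    penalty: float = 1.0
    max_iter: int = 50
    tol: float = 1e-8
    bootstrap_ci: bool = False
    # stratification
    by_sex: bool = True
    by_residence: bool = True
    by_region: bool = False
    # summaries
    infant_separation: bool = False
    n_draws: int = 1000
    # simulation
    n_households: int = 2000
    homogeneity: float = 0.9
    indigenous_rate_ratio: float = 2.0
    censor_single_person_deaths: bool = False
    # run control
    seed: int = 0
    log_level: str = "INFO"

    def digest(self) -> str:
        """Short stable hash of the configuration, for the run log."""
        payload = {f.name: getattr(self, f.name) for f in fields(self)}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_KNOWN_KEYS = {f.name for f in fields(RunConfig)}


def _coerce(key: str, value: Any) -> Any:
    if key == "knots" and value is not None:
        if isinstance(value, str):
            value = [int(v) for v in value.split(",")]
        return tuple(int(v) for v in value)
    return value


def parse_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Build a validated RunConfig from an optional YAML file plus overrides.

    Overrides with value ``None`` are ignored (unset flags); unknown keys in
    either source raise :class:`ConfigurationError` naming the key.
    """
    values: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must be a flat mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(values) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {sorted(unknown)}; "
            f"known keys are {sorted(_KNOWN_KEYS)}"
        )
    values = {k: _coerce(k, v) for k, v in values.items()}
    config = RunConfig(**values)
    if config.typology not in (1, 2, 3, 4):
        raise ConfigurationError(f"typology must be 1-4, got {config.typology}")
    if config.penalty < 0:
        raise ConfigurationError("penalty must be non-negative")
    if not 0.0 <= config.homogeneity <= 1.0:
        raise ConfigurationError("homogeneity must lie in [0, 1]")
    return config
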