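"""Reading and writing the package's delimited-text formats.

Trial tables are plain CSV with the fixed header
``subject,site,task,contrast,stimulus,response,correct,pas``; configuration
files are declarative YAML mapping directly onto the config dataclasses.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .observer import TRIAL_COLUMNS, CohortConfig

__all__ = [
    "read_trials",
    "write_trials",
    "validate_trials",
    "load_cohort_config",
    "dump_cohort_config",
]


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the documented schema."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise DataError(f"trial table missing columns: {missing}")
    t = trials.loc[:, list(TRIAL_COLUMNS)].copy()
    t["stimulus"] = t["stimulus"].astype(int)
    t["response"] = t["response"].astype(int)
    t["pas"] = t["pas"].astype(int)
    t["correct"] = t["correct"].astype(bool)
    if not np.isin(t["stimulus"], (-1, 1)).all() or not np.isin(t["response"], (-1, 1)).all():
        raise DataError("stimulus/response must be -1 or +1")
    if (t["pas"] < 1).any() or (t["pas"] > 4).any():
        raise DataError("pas must be in 1..4")
    if not (t["correct"] == (t["stimulus"] == t["response"])).all():
        raise DataError("correct flag inconsistent with stimulus == response")
    return t


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy trial table from CSV."""
    return validate_trials(pd.read_csv(path))


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    validate_trials(trials).to_csv(path, index=False)


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("cohort config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
    for key in ("contrasts", "sites", "tasks", "site_effect"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "population" in raw:
        raw["population"] = {k: tuple(v) for k, v in raw["population"].items()}
    return CohortConfig(**raw)


def dump_cohort_config(config: CohortConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["contrasts"] = list(config.contrasts)
    d["sites"] = list(config.sites)
    d["tasks"] = list(config.tasks)
    d["site_effect"] = list(config.site_effect)
    d["population"] = {k: list(v) for k, v in config.population.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
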