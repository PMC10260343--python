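"""Configuration and file round-tripping shared by the CLI and the library.

File formats are deliberately plain:

* scenario CSV — header ``row,level,prob``, one record per combination,
  grid shape inferred, 1-based indices;
* trial CSV — header ``patient,row,level,dlt``, 1-based indices, dlt in {0,1};
* config — YAML or JSON mapping with the design keys below.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import Combination, ToxScenario, validate_scenario
from .design import ShiftCrmConfig, TrialState
from .errors import ConfigError, TrialDataError

#: config keys, their types, and defaults (None = required... all optional here)
_CONFIG_FIELDS = {
    "target": (float, 0.30),
    "n_max": (int, 39),
    "shifts": (tuple, (0, -1)),
    "halfwidth": (float, 0.05),
    "prior_mtd": (int, 4),
    "n_rows": (int, 2),
    "n_levels": (int, 7),
    "safety_confidence": (float, 0.90),
    "safety_min_exposure": (int, 3),
    "max_step": (int, None),
    "seed": (int, 0),
    "n_trials": (int, 1000),
    "out_dir": (str, "."),
}


@dataclass(frozen=True)
class RunConfig:
    """Merged design + simulation settings resolved from a config file."""

    design: ShiftCrmConfig
    seed: int = 0
    n_trials: int = 1000
    out_dir: str = "."

    def to_dict(self) -> dict:
        d = {
            "target": self.design.target,
            "n_max": self.design.n_max,
            "shifts": list(self.design.shifts),
            "halfwidth": self.design.halfwidth,
            "prior_mtd": self.design.prior_mtd,
            "n_rows": self.design.n_rows,
            "n_levels": self.design.n_levels,
            "safety_confidence": self.design.safety_confidence,
            "safety_min_exposure": self.design.safety_min_exposure,
            "max_step": self.design.max_step,
            "seed": self.seed,
            "n_trials": self.n_trials,
            "out_dir": self.out_dir,
        }
        return d


def load_config(path) -> RunConfig:
    """Parse, default, and validate a YAML/JSON configuration file.

    Unknown keys are rejected so that typos fail loudly rather than being
    silently ignored.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - set(_CONFIG_FIELDS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    merged = {}
    for key, (typ, default) in _CONFIG_FIELDS.items():
        value = raw.get(key, default)
        if value is None:
            merged[key] = None
            continue
        try:
            merged[key] = tuple(int(v) for v in value) if typ is tuple else typ(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key {key!r}: expected {typ.__name__}, got {value!r}") from exc
    try:
        design = ShiftCrmConfig(
            target=merged["target"],
            n_max=merged["n_max"],
            shifts=merged["shifts"],
            halfwidth=merged["halfwidth"],
            prior_mtd=merged["prior_mtd"],
            n_rows=merged["n_rows"],
            n_levels=merged["n_levels"],
            safety_confidence=merged["safety_confidence"],
            safety_min_exposure=merged["safety_min_exposure"],
            max_step=merged["max_step"],
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(
        design=design,
        seed=merged["seed"],
        n_trials=merged["n_trials"],
        out_dir=merged["out_dir"],
    )


def dump_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def read_trial_csv(path, config: Optional[ShiftCrmConfig] = None) -> TrialState:
    """Ordered TrialState from a ``patient,row,level,dlt`` CSV.

    The conduct stage is derived from the heterogeneity rule; an empty file
    yields an empty initial-stage state.
    """
    config = config or ShiftCrmConfig()
    state = TrialState(grid=config.grid())
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return state
    if df.empty:
        return state
    required = ["patient", "row", "level", "dlt"]
    if list(df.columns) != required:
        raise TrialDataError(f"trial CSV must have header {','.join(required)}")
    if df["patient"].duplicated().any():
        raise TrialDataError("duplicate patient index in trial CSV")
    df = df.sort_values("patient")
    if list(df["patient"]) != list(range(1, len(df) + 1)):
        raise TrialDataError("patient indices must be consecutive from 1")
    for _, rec in df.iterrows():
        if int(rec["dlt"]) not in (0, 1):
            raise TrialDataError(f"patient {rec['patient']}: dlt must be 0 or 1")
        combo = Combination(int(rec["row"]), int(rec["level"]))
        if not state.grid.contains(combo):
            raise TrialDataError(f"patient {rec['patient']}: {combo} outside the grid")
        state.add(combo, int(rec["dlt"]))
    return state


def write_trial_csv(state: TrialState, path) -> None:
    pd.DataFrame(
        {
            "patient": [r.patient for r in state.records],
            "row": [r.combination.row for r in state.records],
            "level": [r.combination.level for r in state.records],
            "dlt": [r.dlt for r in state.records],
        }
    ).to_csv(path, index=False)


def read_scenario_csv(path, target: float = 0.30, max_shift: int = 1) -> ToxScenario:
    """Validated ToxScenario from a ``row,level,prob`` CSV (shape inferred)."""
    df = pd.read_csv(path)
    if list(df.columns) != ["row", "level", "prob"]:
        raise TrialDataError("scenario CSV must have header row,level,prob")
    n_rows = int(df["row"].max())
    n_levels = int(df["level"].max())
    probs = np.full((n_rows, n_levels), np.nan)
    for _, rec in df.iterrows():
        probs[int(rec["row"]) - 1, int(rec["level"]) - 1] = float(rec["prob"])
    if np.isnan(probs).any():
        raise TrialDataError("scenario CSV does not cover the full grid")
    name = Path(path).stem
    return validate_scenario(ToxScenario(probs=probs, target=target, name=name), max_shift)


def write_scenario_csv(scenario: ToxScenario, path) -> None:
    rows, levels = np.indices(scenario.probs.shape)
    pd.DataFrame(
        {
            "row": rows.ravel() + 1,
            "level": levels.ravel() + 1,
            "prob": scenario.probs.ravel(),
        }
    ).to_csv(path, index=False)
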