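"""Flat-file I/O: trial tables as CSV, parameters as JSON/YAML."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .models import DDMParams
from .simulate import TRIAL_COLUMNS

__all__ = ["write_trials", "read_trials", "write_params", "read_params",
           "read_fits"]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table; ``rt_s`` is empty for misses."""
    out = trials[TRIAL_COLUMNS].copy()
    out["mask"] = out["mask"].astype(int)
    out["filler"] = out["filler"].astype(bool)
    out.to_csv(path, index=False, float_format="%.6f")


def read_trials(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial table not found: {path}")
    t = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"trial table {path} lacks columns {sorted(missing)}")
    t["filler"] = t["filler"].astype(bool)
    return t


def read_fits(path: str | Path) -> pd.DataFrame:
    """Read a fit-results table; the model name 'null' must survive
    (pandas would otherwise parse it as missing)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"fit table not found: {path}")
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def write_params(params: DDMParams | dict, path: str | Path) -> None:
    d = params.to_dict() if isinstance(params, DDMParams) else dict(params)
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(d, fh, sort_keys=False)
        else:
            json.dump(d, fh, indent=2)


def read_params(path: str | Path) -> DDMParams:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    with open(path) as fh:
        d = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    return DDMParams(**d)
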