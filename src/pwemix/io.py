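"""Tabular I/O and run manifests.

Data tables are comma-separated UTF-8 text with a mandatory header row
and empty fields for missing values; reports are tab-separated.  Floats
round-trip at full precision (17 significant digits).  Every pipeline
run writes a manifest (config hash, package and library versions, seed,
row counts) sufficient to reproduce it exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

__all__ = ["read_table", "write_table", "write_report", "load_config",
           "config_hash", "write_manifest"]

_FLOAT_FMT = "%.17g"


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")
    return path


def write_report(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, sep="\t", float_format=_FLOAT_FMT, na_rep="")
    return path


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int | None,
                   row_counts: dict[str, int]) -> Path:
    from . import __version__

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "row_counts": row_counts,
        "versions": {
            "pwemix": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
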