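"""Delimited-text I/O helpers shared by the CLI and the pipeline driver.

All outputs are plain CSV with a leading ``#``-comment header that records
units, the package version and the seed/config hash that generated the file;
all readers therefore pass ``comment='#'``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["config_hash", "write_csv", "read_csv", "load_config",
           "write_draws", "read_draws"]


def config_hash(obj) -> str:
    """Short stable hash of a configuration object (dataclass or mapping)."""
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, meta: str = "", index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# hetvar: {meta}\n")
        df.to_csv(fh, index=index)


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def load_config(path) -> dict:
    """YAML config file -> nested dict (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


def write_draws(draws, path, meta: str = "") -> None:
    """Retained variance draws of one analysis as CSV (kg^2 columns)."""
    df = draws.draws.copy()
    df.insert(0, "draw", range(1, len(df) + 1))
    write_csv(df, path, meta=meta or
              f"model={draws.model} seed={draws.chain.seed} "
              f"cycles={draws.chain.cycles} burnin={draws.chain.burnin} "
              f"thin={draws.chain.thin} units=kg^2")


def read_draws(path) -> pd.DataFrame:
    df = read_csv(path)
    return df.drop(columns=[c for c in ("draw",) if c in df.columns])
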