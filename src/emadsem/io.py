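"""Reading/writing the long-format EMA CSV and the YAML configuration."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import GenDesign, GenParams

__all__ = ["read_ema_csv", "write_ema_csv", "load_config", "save_config"]


def write_ema_csv(records: pd.DataFrame, path) -> None:
    """One row per scheduled prompt; missing encoded as empty field; UTF-8."""
    records.to_csv(path, index=False, encoding="utf-8")


def read_ema_csv(path) -> pd.DataFrame:
    records = pd.read_csv(path, encoding="utf-8")
    for col in ("person_id", "prompt_index"):
        if col in records.columns:
            records[col] = records[col].astype(int)
    if "observed" in records.columns:
        records["observed"] = records["observed"].astype(bool)
    return records


def _to_plain(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list, np.ndarray)):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(path, design: GenDesign, params: GenParams) -> None:
    cfg = {
        "design": _to_plain(dataclasses.asdict(design)),
        "params": _to_plain(dataclasses.asdict(params)),
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False), encoding="utf-8")


def _tupleize(value):
    if isinstance(value, list):
        return tuple(_tupleize(v) for v in value)
    return value


def load_config(path) -> tuple[GenDesign, GenParams]:
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    dsec = {k: _tupleize(v) for k, v in (cfg.get("design") or {}).items()}
    psec = {k: _tupleize(v) for k, v in (cfg.get("params") or {}).items()}
    return GenDesign(**dsec), GenParams(**psec)
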