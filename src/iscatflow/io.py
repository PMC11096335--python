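"""Disk formats: TIFF tile stacks with JSON sidecars, CSV tables, YAML configs.

A simulated or recorded scan is stored as

* ``<stem>.tif``  -- multi-page TIFF, one page per tile (float32);
* ``<stem>.json`` -- sidecar with pixel pitch, nominal/true tile offsets and
  the seed;
* ``<stem>.truth.csv`` -- optional seeded ground-truth table.

Localisation tables go to CSV with the canonical column set.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .instrument import InstrumentConfig
from .locfind import DetectionConfig, LOCALIZATION_COLUMNS


def write_scan(stem: str | Path, tiles, nominal_offsets,
               pitch_um: float,
               true_offsets=None,
               truth: pd.DataFrame | None = None,
               seed: int | None = None) -> None:
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".tif"),
                     np.stack([np.asarray(t, dtype=np.float32) for t in tiles]))
    sidecar = {
        "pitch_um": pitch_um,
        "nominal_offsets": np.asarray(nominal_offsets).tolist(),
        "seed": seed,
    }
    if true_offsets is not None:
        sidecar["true_offsets"] = np.asarray(true_offsets).tolist()
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    if truth is not None:
        truth.to_csv(stem.with_suffix(".truth.csv"), index=False)


def read_scan(stem: str | Path):
    """Returns (tiles list, nominal_offsets, sidecar dict, truth or None)."""
    stem = Path(stem)
    stack = tifffile.imread(stem.with_suffix(".tif"))
    if stack.ndim == 2:
        stack = stack[None]
    tiles = [np.asarray(p, dtype=float) for p in stack]
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    offsets = np.asarray(sidecar["nominal_offsets"])
    truth_path = stem.with_suffix(".truth.csv")
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return tiles, offsets, sidecar, truth


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in LOCALIZATION_COLUMNS if c in table.columns]
    table[cols + [c for c in table.columns if c not in cols]].to_csv(
        path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_config(cfg, path: str | Path) -> None:
    """Serialise an InstrumentConfig or DetectionConfig to YAML."""
    data = dataclasses.asdict(cfg)
    data["__type__"] = type(cfg).__name__
    Path(path).write_text(yaml.safe_dump(data))


def load_config(path: str | Path):
    data = yaml.safe_load(Path(path).read_text())
    kind = data.pop("__type__")
    cls = {"InstrumentConfig": InstrumentConfig,
           "DetectionConfig": DetectionConfig}[kind]
    if kind == "InstrumentConfig" and "frame_shape" in data:
        data["frame_shape"] = tuple(data["frame_shape"])
    return cls(**data)
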