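"""Snapshot tables, mask images, and run manifests as plain-text files."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, config_to_dict
from .engine import SNAPSHOT_COLUMNS


def write_snapshot(snapshot: pd.DataFrame, path: str | Path) -> None:
    snapshot.to_csv(path, sep="\t", index=False)


def read_snapshot(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genome": str}, keep_default_na=False)
    missing = set(SNAPSHOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"snapshot table missing columns {sorted(missing)}")
    return df


def write_pgm(mask: np.ndarray, path: str | Path, maxval: int = 255) -> None:
    """Binary mask as a plain (ASCII, P2) portable graymap."""
    arr = (np.asarray(mask).astype(bool) * maxval).astype(int)
    h, w = arr.shape
    with open(path, "w") as fh:
        fh.write(f"P2\n{w} {h}\n{maxval}\n")
        for row in arr:
            fh.write(" ".join(map(str, row)) + "\n")


def write_matrix(field: np.ndarray, path: str | Path) -> None:
    """Scalar field (e.g. the ISF) as whitespace-delimited text."""
    np.savetxt(path, np.asarray(field), fmt="%.6g")


def config_hash(cfg: SimulationConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(cfg: SimulationConfig, path: str | Path, **extra) -> None:
    manifest = {
        "config": config_to_dict(cfg),
        "config_hash": config_hash(cfg),
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
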