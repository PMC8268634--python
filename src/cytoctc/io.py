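"""On-disk formats: multi-page TIFF images with CSV/JSON sidecars.

A simulated slide is written as ``image.tiff`` (one float32 page per
channel, DAPI first), ``ground_truth.csv`` (one row per planted cell) and
``params.json`` (channels, pixel size, seed, noise).  Cohorts are written
as ``patients.csv`` and ``cells.csv``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import CHANNELS, ImageGroundTruth

__all__ = [
    "save_image_bundle",
    "load_image_bundle",
    "save_cohort",
    "load_cohort",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_image_bundle(out_dir: str | Path, gt: ImageGroundTruth) -> Path:
    """Write image.tiff + ground_truth.csv + params.json; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "image.tiff", gt.image, metadata={"axes": "CYX"})
    gt.to_frame().to_csv(out / "ground_truth.csv", index=False)
    sidecar = {
        "channels": list(CHANNELS),
        "pixel_size_um": gt.pixel_size_um,
        "seed": gt.seed,
        "background_level": gt.background_level,
        "noise_sd": gt.noise_sd,
        "params": _jsonable(gt.params),
    }
    (out / "params.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_image_bundle(bundle_dir: str | Path) -> tuple[np.ndarray, dict]:
    """Read image.tiff and its params.json sidecar back."""
    d = Path(bundle_dir)
    image = tifffile.imread(d / "image.tiff")
    meta = json.loads((d / "params.json").read_text())
    return np.asarray(image), meta


def save_cohort(out_dir: str | Path, patients: pd.DataFrame, cells: pd.DataFrame) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients.to_csv(out / "patients.csv", index=False)
    cells.to_csv(out / "cells.csv", index=False)
    return out


def load_cohort(cohort_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    d = Path(cohort_dir)
    return pd.read_csv(d / "patients.csv"), pd.read_csv(d / "cells.csv")
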