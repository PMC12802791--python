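"""File-format plumbing: 8-bit PNG images/masks, CSV manifests, JSON summaries.

Masks live in memory as ``uint8`` arrays with values in {0, 1} and on disk as
8-bit grayscale PNGs with values in {0, 255}; the round trip is lossless.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "read_image_png",
    "write_image_png",
    "read_mask_png",
    "write_mask_png",
    "read_manifest",
    "write_manifest",
    "read_metrics_csv",
    "write_metrics_csv",
    "read_summary_json",
    "write_summary_json",
    "write_provenance",
    "config_fingerprint",
]

MANIFEST_COLUMNS = ["id", "image_path", "clot_mask_path", "dot_mask_path", "seed"]
METRICS_COLUMNS = ["id", "mean_iou_2class", "clot_iou", "auroc", "accuracy"]


def write_image_png(path: str | Path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError(f"expected uint8 image, got {image.dtype}")
    Image.fromarray(image, mode="L" if image.ndim == 2 else "RGB").save(path)


def read_image_png(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("mask values must be in {0, 1}")
    write_image_png(path, (mask.astype(np.uint8) * 255))


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = read_image_png(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel mask PNG")
    vals = np.unique(arr)
    if not np.isin(vals, [0, 255]).all():
        raise ValueError(f"{path}: mask PNG must contain only {{0, 255}}, found {vals[:10]}")
    return (arr > 0).astype(np.uint8)


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns {missing}")
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    path = Path(path)
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"{path}: manifest is missing columns {missing}")
    if check_files:
        base = path.parent
        for row in manifest.itertuples():
            for col in ("image_path", "clot_mask_path", "dot_mask_path"):
                p = base / getattr(row, col)
                if not p.is_file():
                    raise FileNotFoundError(
                        f"{path}: row id={row.id} references missing file {p}"
                    )
    return manifest


def write_metrics_csv(path: str | Path, metrics: list) -> None:
    """Write per-image metric records (dataclasses or dicts) to CSV."""
    rows = [dataclasses.asdict(m) if dataclasses.is_dataclass(m) else dict(m) for m in metrics]
    df = pd.DataFrame(rows)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics records are missing fields {missing}")
    df[METRICS_COLUMNS].to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metrics CSV is missing columns {missing}")
    return df[METRICS_COLUMNS]


def write_summary_json(path: str | Path, summary: Any) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    Path(path).write_text(Path(path).read_text() + "\n")


def read_summary_json(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_fingerprint(config: Any) -> str:
    """Stable short hash of a (nested) configuration object."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: str | Path, *, stage: str, seed: int | None, config: Any) -> None:
    """Record which seed and configuration produced the artifacts in a directory."""
    write_summary_json(
        path,
        {
            "stage": stage,
            "seed": seed,
            "config_fingerprint": config_fingerprint(config),
            "config": config,
        },
    )
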