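"""Raster and table I/O.

Label masks travel as single-channel integer rasters: 8-bit PNG, TIFF
(any integer depth) or ``.npy``.  RGB color-coded masks are accepted and
converted through the legend's color table.  Manifests and clinical
tables are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ConfigError, LegendError
from .masks import ClassLegend, TissueMask, mask_from_rgb

MANIFEST_COLUMNS = ("case_id", "slide_id", "mask_path")


def read_mask(
    path: str | Path, legend: ClassLegend, origin_slide: str | None = None
) -> TissueMask:
    """Read a label raster (PNG/TIFF/npy; RGB masks converted via legend)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        arr = np.load(path)
    elif suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        return mask_from_rgb(arr, legend, origin_slide=origin_slide)
    if not np.issubdtype(arr.dtype, np.integer):
        raise LegendError(f"{path}: mask raster must be integer, got {arr.dtype}")
    return TissueMask(
        labels=arr.astype(np.int64), legend=legend, origin_slide=origin_slide
    )


def write_mask(mask: TissueMask, path: str | Path) -> None:
    """Write a label raster as PNG (ids < 256), TIFF or npy."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, mask.labels)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.labels.astype(np.uint16))
    elif suffix == ".png":
        if mask.labels.max() > 255:
            raise ConfigError("PNG masks support class ids up to 255 only")
        Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(path)
    else:
        raise ConfigError(f"unsupported mask format: {path.suffix!r}")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a slide manifest CSV (case_id, slide_id, mask_path[, subtype_mask_path])."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"manifest is missing columns: {missing}")
    if df["slide_id"].duplicated().any():
        dup = df.loc[df["slide_id"].duplicated(), "slide_id"].tolist()
        raise ConfigError(f"duplicate slide_ids in manifest: {dup}")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical CSV with case_id, per-endpoint time/event columns, pT/pN."""
    df = pd.read_csv(path)
    if "case_id" not in df.columns:
        raise ConfigError("clinical table must contain a case_id column")
    return df
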