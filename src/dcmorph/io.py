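"""Thin I/O helpers: TIFF masks/stacks, contour CSVs, run configs."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_mask",
    "read_stack",
    "write_mask",
    "write_stack",
    "read_contour_csv",
    "load_config",
]


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-frame TIFF mask; nonzero pixels are foreground."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D mask, got shape {arr.shape}")
    return arr


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-frame TIFF as a (T, H, W) array (2D input gains T=1)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D/3D TIFF, got shape {arr.shape}")
    return arr


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary/label mask as 8-bit TIFF (labels >255 kept 16-bit)."""
    m = np.asarray(mask)
    dtype = np.uint8 if m.max(initial=0) <= 255 else np.uint16
    tifffile.imwrite(str(path), m.astype(dtype))


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (T, H, W) stack as multi-frame TIFF."""
    s = np.asarray(stack)
    if s.dtype.kind == "f":
        s = s.astype(np.uint16)
    elif s.max(initial=0) <= 255:
        s = s.astype(np.uint8)
    else:
        s = s.astype(np.uint16)
    tifffile.imwrite(str(path), s)


def read_contour_csv(path: str | Path) -> np.ndarray:
    """Read an (x_um, y_um) contour table into an (n, 2) array."""
    df = pd.read_csv(path)
    for col in ("x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: contour CSV needs column {col!r}")
    return df[["x_um", "y_um"]].to_numpy(dtype=float)


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def iter_tiffs(directory: str | Path) -> Iterable[Path]:
    """Sorted TIFF files directly under `directory`."""
    d = Path(directory)
    return sorted(p for p in d.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
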