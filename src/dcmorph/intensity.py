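"""Per-cell fluorescence quantification.

Implements the measurement rules used for reporter read-outs in confined
dendritic cells: pick the imaging plane that contains the nucleus, measure
mean intensities over a nucleus mask (DNA channel) and a cell mask
(actin/phalloidin channel), form the nucleus-to-cytosol ratio, and keep
only cells whose mean signal exceeds the image background ("gated" means).

Ratios are ratios of region means (not means of pixel ratios), the cytosol
is the cell mask minus the nucleus mask, and the background estimate is the
median of pixels outside all (dilated) cell masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "IntensityRecord",
    "select_nucleus_plane",
    "nucleus_cytosol_ratio",
    "gated_mean_intensity",
    "estimate_background",
]


class IntensityError(ValueError):
    """Raised for unusable masks or images."""


@dataclass(frozen=True)
class IntensityRecord:
    """Mean intensities and derived statistics for one cell."""

    cell_id: int
    nuclear_mean: Optional[float] = None
    cytosol_mean: Optional[float] = None
    cell_mean: Optional[float] = None
    ratio_nuc_cyt: Optional[float] = None
    background: Optional[float] = None
    passes_background_gate: Optional[bool] = None


def select_nucleus_plane(nucleus_masks: np.ndarray) -> int:
    """Index of the z-plane where the nucleus mask is largest.

    `nucleus_masks` is a (Z, H, W) boolean/label stack.  Ties break to the
    lowest index; a stack with no nucleus anywhere is an error.
    """
    stack = np.asarray(nucleus_masks)
    if stack.ndim != 3:
        raise ValueError("nucleus_masks must be (Z, H, W)")
    areas = (stack > 0).sum(axis=(1, 2))
    if areas.max() == 0:
        raise IntensityError("no nucleus found in any plane")
    return int(np.argmax(areas))  # argmax returns first maximum


def nucleus_cytosol_ratio(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    cell_id: int = 1,
) -> IntensityRecord:
    """Nucleus-to-cytosol intensity ratio of one cell.

    nuclear_mean is the image mean over the nucleus mask, cytosol_mean over
    cell-minus-nucleus, and the ratio their quotient.  The nucleus must be
    contained in the cell and the cytosol non-empty.
    """
    img = np.asarray(image, dtype=float)
    nuc = np.asarray(nucleus_mask) > 0
    cell = np.asarray(cell_mask) > 0
    if not (img.shape == nuc.shape == cell.shape):
        raise ValueError("image and masks must share one shape")
    if not nuc.any():
        raise IntensityError("empty nucleus mask")
    if np.any(nuc & ~cell):
        raise IntensityError("nucleus mask extends outside the cell mask")
    cyto = cell & ~nuc
    if not cyto.any():
        raise IntensityError("cytosol region (cell minus nucleus) is empty")
    nuclear_mean = float(img[nuc].mean())
    cytosol_mean = float(img[cyto].mean())
    ratio = nuclear_mean / cytosol_mean if cytosol_mean > 0 else None
    return IntensityRecord(
        cell_id=cell_id,
        nuclear_mean=nuclear_mean,
        cytosol_mean=cytosol_mean,
        cell_mean=float(img[cell].mean()),
        ratio_nuc_cyt=ratio,
    )


def gated_mean_intensity(
    image: np.ndarray,
    cell_masks: Sequence[np.ndarray] | np.ndarray,
    background: float,
) -> pd.DataFrame:
    """Mean intensity per cell outline with a background gate.

    `cell_masks` is either a sequence of binary masks or a label image.
    Every cell gets a row with its mean; ``passes_background_gate`` is True
    when the mean strictly exceeds `background` — only those cells would be
    plotted.

    Returns a DataFrame (cell_id, cell_mean, background,
    passes_background_gate).
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    img = np.asarray(image, dtype=float)
    if isinstance(cell_masks, np.ndarray) and cell_masks.ndim == 2 and (
        cell_masks.dtype.kind in "iu" and cell_masks.max() > 1
    ):
        labels = np.asarray(cell_masks, dtype=int)
        ids = [int(i) for i in np.unique(labels) if i > 0]
        masks = [(labels == i) for i in ids]
    else:
        masks = [np.asarray(m) > 0 for m in cell_masks]
        ids = list(range(1, len(masks) + 1))
    rows = []
    for cid, m in zip(ids, masks):
        if m.shape != img.shape:
            raise ValueError("mask shape does not match image")
        if not m.any():
            raise IntensityError(f"cell {cid}: empty outline")
        mean = float(img[m].mean())
        rows.append(
            dict(
                cell_id=cid,
                cell_mean=mean,
                background=float(background),
                passes_background_gate=mean > background,
            )
        )
    return pd.DataFrame(rows)


def estimate_background(
    image: np.ndarray,
    all_cell_mask: np.ndarray,
    dilation_px: int = 5,
    min_fraction: float = 0.01,
) -> float:
    """Median intensity outside all cells.

    Cell masks are dilated by `dilation_px` (to exclude halo pixels) and the
    median of the remaining pixels returned.  Errors if fewer than
    `min_fraction` of the image remains as background.
    """
    img = np.asarray(image, dtype=float)
    cells = np.asarray(all_cell_mask) > 0
    if cells.shape != img.shape:
        raise ValueError("mask shape does not match image")
    if dilation_px > 0:
        cells = ndi.binary_dilation(
            cells, structure=ndi.generate_binary_structure(2, 2),
            iterations=dilation_px,
        )
    bg = ~cells
    if bg.sum() < min_fraction * img.size:
        raise IntensityError(
            "background region smaller than "
            f"{min_fraction:.0%} of the image — cannot estimate background"
        )
    return float(np.median(img[bg]))
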