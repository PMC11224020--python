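"""Cell-diameter dynamics from timelapse masks: skeleton × distance map.

The width of an elongated migrating cell is read off a binary mask by
(1) thinning the mask to its one-pixel skeleton, (2) computing the exact
Euclidean distance transform (each foreground pixel's distance to the
nearest background pixel), and (3) sampling the distance map along the
skeleton.  Twice the sampled distance is the local cell diameter; the
per-frame minimum, mean and maximum summarize the frame, and per-cell
values average those over the track.

Residence fractions report how much of a track's duration the cell spends
with its minimum diameter in a bin — by default [2, 4) µm versus [4, inf) —
the regime in which dendritic cells patrolling skin are strongly deformed.

Tracking is greedy nearest-centroid linking with a displacement gate; it
stands in for manual per-cell tracking and is deterministic given input
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as _skmeasure
from skimage.morphology import skeletonize

__all__ = [
    "FrameDiameters",
    "ResidenceSummary",
    "Track",
    "frame_diameters",
    "stack_diameters",
    "cell_time_average",
    "residence_fractions",
    "track_cells",
    "track_speed",
]


class DiameterError(ValueError):
    """Raised for masks the diameter pipeline cannot measure."""


@dataclass(frozen=True)
class FrameDiameters:
    """Min / mean / max diameter of one cell in one frame, µm."""

    min_um: float
    mean_um: float
    max_um: float
    touches_border: bool = False
    unresolved: bool = False  # min diameter below 2 pixels

    def __post_init__(self) -> None:
        assert self.min_um <= self.mean_um <= self.max_um


@dataclass(frozen=True)
class ResidenceSummary:
    """Fractions of track time spent per minimum-diameter bin."""

    fraction_2to4: float
    fraction_gt4: float
    total_time_min: float


@dataclass(frozen=True)
class Track:
    """Centroid trajectory of one cell across frames."""

    cell_id: int
    frames: np.ndarray  # strictly increasing frame indices
    centroids_um: np.ndarray  # (n, 2) (x, y) µm
    frame_interval: float  # minutes

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=int)
        c = np.asarray(self.centroids_um, dtype=float)
        if len(f) != len(c):
            raise ValueError("frames and centroids must have equal length")
        if len(f) and np.any(np.diff(f) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "centroids_um", c)

    @property
    def duration_min(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return float(self.frames[-1] - self.frames[0]) * self.frame_interval


def _prune_endpoints(skel: np.ndarray, n_iter: int) -> np.ndarray:
    """Iteratively strip skeleton endpoints (simple spur pruning)."""
    sk = skel.copy()
    kernel = np.ones((3, 3), dtype=int)
    for _ in range(n_iter):
        neighbors = ndi.convolve(sk.astype(int), kernel, mode="constant") - sk
        endpoints = sk & (neighbors <= 1)
        if not endpoints.any():
            break
        sk &= ~endpoints
    return sk


def frame_diameters(
    mask: np.ndarray,
    pixel_size: float | tuple[float, float],
    prune_px: int = 0,
) -> FrameDiameters:
    """Diameter statistics of one single-cell mask.

    Skeletonize the mask, sample the exact Euclidean distance transform at
    skeleton pixels, and return 2x those distances (min/mean/max) in µm.
    Skeleton branch points and endpoints are kept by default; `prune_px`
    iterations of endpoint removal are available because end-cap spurs bias
    the minimum low on blob-like cells.

    Raises on empty/multi-component masks and anisotropic pixels; flags
    (not errors) masks touching the border or thinner than 2 pixels.
    """
    if np.ndim(pixel_size) > 0:
        ps = tuple(float(p) for p in np.atleast_1d(pixel_size))
        if len(ps) != 1 and (len(ps) != 2 or ps[0] != ps[1]):
            raise DiameterError(
                f"anisotropic pixels {ps} are not supported; resample first"
            )
        pixel_size = ps[0]
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    m = np.asarray(mask) > 0
    if not m.any():
        raise DiameterError("empty mask")
    _, n = _skmeasure.label(m, return_num=True, connectivity=2)
    if n != 1:
        raise DiameterError(f"expected 1 foreground component, found {n}")
    touches = bool(
        m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any()
    )
    skel = skeletonize(m)
    if prune_px > 0:
        pruned = _prune_endpoints(skel, prune_px)
        if pruned.any():
            skel = pruned
    if not skel.any():
        raise DiameterError("skeleton is empty")
    edt = ndi.distance_transform_edt(m)
    diams = 2.0 * edt[skel] * pixel_size
    dmin = float(diams.min())
    dmax = float(diams.max())
    # np.mean can overshoot the extremes by one ulp on constant input
    dmean = float(np.clip(diams.mean(), dmin, dmax))
    return FrameDiameters(
        min_um=dmin,
        mean_um=dmean,
        max_um=dmax,
        touches_border=touches,
        unresolved=dmin < 2.0 * pixel_size + 1e-12,
    )


def stack_diameters(
    stack: np.ndarray,
    pixel_size: float,
    cell_id: int = 1,
    prune_px: int = 0,
) -> pd.DataFrame:
    """Per-frame diameters of a (T, H, W) binary single-cell stack."""
    rows = []
    for f, frame in enumerate(stack):
        d = frame_diameters(frame, pixel_size, prune_px=prune_px)
        rows.append(
            dict(
                cell_id=cell_id,
                frame=f,
                min_diam_um=d.min_um,
                mean_diam_um=d.mean_um,
                max_diam_um=d.max_um,
                touches_border=d.touches_border,
                unresolved=d.unresolved,
            )
        )
    return pd.DataFrame(rows)


def cell_time_average(per_frame: pd.DataFrame) -> pd.DataFrame:
    """Average each diameter statistic over a cell's frames.

    Expects columns cell_id, min_diam_um, mean_diam_um, max_diam_um and
    returns one row per cell with the arithmetic mean and, because figure
    summaries sometimes use it, the median of each statistic.
    """
    if per_frame.empty:
        raise ValueError("no frames to average")
    g = per_frame.groupby("cell_id")
    out = g.agg(
        n_frames=("frame", "size"),
        avg_min_um=("min_diam_um", "mean"),
        avg_mean_um=("mean_diam_um", "mean"),
        avg_max_um=("max_diam_um", "mean"),
        median_min_um=("min_diam_um", "median"),
        median_max_um=("max_diam_um", "median"),
    )
    return out.reset_index()


def residence_fractions(
    min_diams_um: Sequence[float],
    frame_interval: float,
    bins_um: tuple[float, float] = (2.0, 4.0),
    min_track_min: float = 40.0,
    enforce_min_duration: bool = True,
) -> ResidenceSummary:
    """Fractions of time spent at a minimum diameter of [2, 4) vs >= 4 µm.

    Each frame contributes `frame_interval` minutes.  The lower bin is the
    half-open interval [bins[0], bins[1]) and the upper bin [bins[1], inf),
    so the two fractions sum to at most 1 (frames thinner than bins[0]
    count toward neither).  Tracks shorter than `min_track_min` are
    rejected unless `enforce_min_duration` is off.
    """
    d = np.asarray(min_diams_um, dtype=float)
    if d.size == 0:
        raise ValueError("no diameters supplied")
    if bins_um[0] >= bins_um[1]:
        raise ValueError("bin edges must be strictly increasing")
    total = d.size * frame_interval
    if enforce_min_duration and total < min_track_min:
        raise ValueError(
            f"track covers {total:.0f} min < required {min_track_min:.0f} min"
        )
    lo = float(np.sum((d >= bins_um[0]) & (d < bins_um[1]))) * frame_interval
    hi = float(np.sum(d >= bins_um[1])) * frame_interval
    return ResidenceSummary(
        fraction_2to4=lo / total,
        fraction_gt4=hi / total,
        total_time_min=total,
    )


def _frame_centroids(frame: np.ndarray, pixel_size: float) -> dict[int, np.ndarray]:
    """Centroids (x, y) µm per label of one frame; labels in sorted order."""
    out: dict[int, np.ndarray] = {}
    for p in _skmeasure.regionprops(np.asarray(frame, dtype=int)):
        r, c = p.centroid
        out[int(p.label)] = np.array([(c + 0.5) * pixel_size, (r + 0.5) * pixel_size])
    return out


def track_cells(
    label_stack: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    max_disp_um: float = 20.0,
) -> list[Track]:
    """Greedy nearest-centroid linking of labelled timelapse frames.

    Open tracks (in creation order) claim their nearest unassigned
    detection in the next frame, provided the displacement is within
    `max_disp_um`; unclaimed detections open new tracks.  A track with no
    admissible detection terminates.  Deterministic given the input stack.
    """
    stack = np.asarray(label_stack)
    if stack.ndim != 3:
        raise ValueError("label_stack must be (T, H, W)")
    tracks: list[dict] = []  # {'frames': [...], 'pts': [...], 'open': bool}
    for f in range(stack.shape[0]):
        dets = _frame_centroids(stack[f], pixel_size)
        det_ids = sorted(dets)
        claimed: set[int] = set()
        for tr in tracks:
            if not tr["open"]:
                continue
            best, best_d = None, np.inf
            for lid in det_ids:
                if lid in claimed:
                    continue
                d = float(np.linalg.norm(dets[lid] - tr["pts"][-1]))
                if d < best_d:
                    best, best_d = lid, d
            if best is not None and best_d <= max_disp_um:
                claimed.add(best)
                tr["frames"].append(f)
                tr["pts"].append(dets[best])
            else:
                tr["open"] = False
        for lid in det_ids:
            if lid not in claimed:
                tracks.append(
                    {"frames": [f], "pts": [dets[lid]], "open": True}
                )
    return [
        Track(
            cell_id=i + 1,
            frames=np.array(tr["frames"]),
            centroids_um=np.array(tr["pts"]),
            frame_interval=frame_interval,
        )
        for i, tr in enumerate(tracks)
    ]


def track_speed(
    track: Track, statistic: Literal["mean", "median"] = "median"
) -> float:
    """Summary of instantaneous speeds (step length / elapsed time), µm/min."""
    if len(track.frames) < 2:
        raise ValueError("speed needs at least 2 track points")
    steps = np.linalg.norm(np.diff(track.centroids_um, axis=0), axis=1)
    dt = np.diff(track.frames) * track.frame_interval
    speeds = steps / dt
    if statistic == "mean":
        return float(np.mean(speeds))
    if statistic == "median":
        return float(np.median(speeds))
    raise ValueError(f"unknown statistic {statistic!r}")
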