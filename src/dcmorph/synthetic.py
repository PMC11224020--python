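"""Synthetic masks, images, trajectories and Ct tables with known ground truth.

Every measurement stage of the package has a matching generator here so the
whole pipeline can be validated against analytic truth without any raw
microscopy:

* star-convex nuclei ``r(theta) = R*(1 + sum_k a_k*cos(k*theta + phi_k))``
  whose area and perimeter have cheap quadrature ground truth — the
  low-frequency cosine terms emulate nuclear-envelope folds ("wrinkles");
* capsule-shaped migrating cells (rectangle with semicircular caps) whose
  width and medial axis are known in closed form, with a per-frame width
  schedule spanning the 2–10 µm range dendritic cells show in skin;
* two-channel stainings with a prescribed nuclear : cytosolic intensity
  ratio under i.i.d. Gaussian noise (intensity ratios are the target here,
  not photon statistics, hence Gaussian rather than Poisson);
* qPCR Ct tables simulated from known expression ratios via
  ``Ct = base - log2(expression) + noise``.

All randomness flows from the explicit ``seed`` carried by each spec; the
same spec always produces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath

from .contours import Contour, ContourError

__all__ = [
    "NucleusSpec",
    "CellTimelapseSpec",
    "IntensitySpec",
    "NucleusTruth",
    "make_nucleus_contour",
    "rasterize_contour",
    "make_nucleus_mask",
    "make_cell_timelapse",
    "combine_label_stacks",
    "make_two_channel_image",
    "make_ct_table",
    "straight_path",
]


# ---------------------------------------------------------------------------
# nuclei


@dataclass(frozen=True)
class NucleusSpec:
    """Star-convex nucleus: radial cosine perturbations of a circle.

    ``fold_amplitudes[k]`` is the dimensionless amplitude of angular
    frequency ``k`` and ``fold_phases[k]`` its phase in radians (default 0).
    Simplicity of the contour is guaranteed by requiring both
    ``sum |a_k| < 1`` (radius stays positive) and ``sum k*|a_k| < 1``.
    """

    base_radius: float  # µm
    fold_amplitudes: Mapping[int, float] = field(default_factory=dict)
    fold_phases: Mapping[int, float] = field(default_factory=dict)
    pixel_size: float = 0.25  # µm / pixel
    image_shape: tuple[int, int] = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        amps = dict(self.fold_amplitudes)
        if any(k < 1 for k in amps):
            raise ValueError("fold frequencies must be >= 1")
        s1 = sum(abs(a) for a in amps.values())
        sk = sum(k * abs(a) for k, a in amps.items())
        if s1 >= 1 or sk >= 1:
            raise ValueError(
                "fold amplitudes too large for a simple contour: "
                f"sum|a_k|={s1:.3f}, sum k|a_k|={sk:.3f} (both must be < 1)"
            )
        rmax = self.base_radius * (1 + s1)
        h, w = self.image_shape
        half_extent = min(h, w) * self.pixel_size / 2.0
        if rmax + 2 * self.pixel_size > half_extent:
            raise ValueError(
                "image too small: contour needs a >= 2 pixel margin "
                f"(max radius {rmax:.2f} µm, half extent {half_extent:.2f} µm)"
            )

    @property
    def center(self) -> tuple[float, float]:
        """Contour center in µm (center of the image frame)."""
        h, w = self.image_shape
        return (w * self.pixel_size / 2.0, h * self.pixel_size / 2.0)


class NucleusTruth(NamedTuple):
    """Analytic ground truth of a generated nucleus contour."""

    area_um2: float
    perimeter_um: float


def _radius(spec: NucleusSpec, theta: np.ndarray) -> np.ndarray:
    r = np.full_like(theta, float(spec.base_radius))
    for k, a in spec.fold_amplitudes.items():
        phi = spec.fold_phases.get(k, 0.0)
        r += spec.base_radius * a * np.cos(k * theta + phi)
    return r


def _radius_deriv(spec: NucleusSpec, theta: np.ndarray) -> np.ndarray:
    dr = np.zeros_like(theta)
    for k, a in spec.fold_amplitudes.items():
        phi = spec.fold_phases.get(k, 0.0)
        dr -= spec.base_radius * a * k * np.sin(k * theta + phi)
    return dr


def make_nucleus_contour(
    spec: NucleusSpec, n_points: int = 720
) -> tuple[Contour, NucleusTruth]:
    """Sample the star-shaped contour and its analytic area/perimeter.

    Area is the exact polar integral ``pi*R^2*(1 + sum a_k^2 / 2)``;
    perimeter is the dense trapezoid quadrature of
    ``integral sqrt(r^2 + r'^2) dtheta`` at 2^17 nodes.
    """
    if n_points < 720:
        raise ValueError("n_points must be >= 720")
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = _radius(spec, theta)
    if np.any(r <= 0):
        raise ValueError("parameterization self-intersects (radius <= 0)")
    cx, cy = spec.center
    v = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    contour = Contour(v)
    if spec.fold_amplitudes and not contour.is_simple():
        raise ValueError("parameterization yields a self-intersecting contour")

    area = np.pi * spec.base_radius**2 * (
        1.0 + 0.5 * sum(a**2 for a in spec.fold_amplitudes.values())
    )
    # periodic trapezoid rule — spectrally accurate for smooth integrands
    td = np.linspace(0.0, 2.0 * np.pi, 1 << 17, endpoint=False)
    rd = _radius(spec, td)
    drd = _radius_deriv(spec, td)
    perim = float(np.sum(np.sqrt(rd**2 + drd**2)) * (td[1] - td[0]))
    return contour, NucleusTruth(area_um2=float(area), perimeter_um=perim)


def rasterize_contour(
    contour: Contour,
    pixel_size: float,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Pixel-center-in-polygon rasterization of a closed contour.

    Pixel (i, j) is foreground iff its center ((j+0.5)*px, (i+0.5)*px) lies
    inside the polygon.  The contour must lie fully inside the frame.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    h, w = image_shape
    v = contour.vertices
    xmax, ymax = w * pixel_size, h * pixel_size
    bad = np.where(
        (v[:, 0] < 0) | (v[:, 0] > xmax) | (v[:, 1] < 0) | (v[:, 1] > ymax)
    )[0]
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"contour exits the frame at vertex {i}: ({v[i, 0]:.3f}, "
            f"{v[i, 1]:.3f}) µm outside {xmax:.3f} x {ymax:.3f} µm"
        )
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    centers = np.column_stack(
        [(jj.ravel() + 0.5) * pixel_size, (ii.ravel() + 0.5) * pixel_size]
    )
    inside = _MplPath(v).contains_points(centers)
    return inside.reshape(h, w).astype(np.uint8)


def make_nucleus_mask(
    spec: NucleusSpec, n_points: int = 720
) -> tuple[np.ndarray, Contour, NucleusTruth]:
    """Contour + rasterized mask + analytic truth in one call."""
    contour, truth = make_nucleus_contour(spec, n_points)
    mask = rasterize_contour(contour, spec.pixel_size, spec.image_shape)
    return mask, contour, truth


# ---------------------------------------------------------------------------
# migrating-cell timelapse


@dataclass(frozen=True)
class CellTimelapseSpec:
    """Capsule-shaped cell whose width and centroid vary per frame.

    ``length`` is the end-to-end extent of the capsule (shaft plus both
    semicircular caps); width is the capsule diameter.  The capsule long
    axis follows the direction of motion (horizontal when stationary).
    """

    n_frames: int
    frame_interval: float  # minutes
    width_schedule: Sequence[float]  # µm per frame
    length: float  # µm, tip-to-tip
    centroid_path: Sequence[tuple[float, float]]  # µm
    pixel_size: float = 0.25
    image_shape: tuple[int, int] = (160, 256)
    cell_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if len(self.width_schedule) != self.n_frames:
            raise ValueError("width_schedule length must equal n_frames")
        if len(self.centroid_path) != self.n_frames:
            raise ValueError("centroid_path length must equal n_frames")
        for wu in self.width_schedule:
            if not (0.5 < wu < 20.0):
                raise ValueError(f"width {wu} µm outside the (0.5, 20) µm range")
            if wu > self.length:
                raise ValueError("width must not exceed capsule length")
        h, w = self.image_shape
        margin = self.length / 2.0 + 1e-9
        for x, y in self.centroid_path:
            if not (
                margin <= x <= w * self.pixel_size - margin
                and self.length / 2 <= y <= h * self.pixel_size - margin
            ):
                raise ValueError(
                    f"centroid ({x:.2f}, {y:.2f}) µm puts the cell outside "
                    "the image bounds"
                )


def _capsule_mask(
    center: tuple[float, float],
    direction: tuple[float, float],
    length: float,
    width: float,
    pixel_size: float,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Pixel centers within width/2 of the capsule's central segment."""
    h, w = image_shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    px = (jj + 0.5) * pixel_size
    py = (ii + 0.5) * pixel_size
    ux, uy = direction
    norm = np.hypot(ux, uy)
    ux, uy = (ux / norm, uy / norm) if norm > 0 else (1.0, 0.0)
    half = max(length - width, 0.0) / 2.0  # shaft half-length
    # projection of each pixel center onto the segment
    dx, dy = px - center[0], py - center[1]
    t = np.clip(dx * ux + dy * uy, -half, half)
    dist = np.hypot(dx - t * ux, dy - t * uy)
    return (dist <= width / 2.0).astype(np.uint8)


def make_cell_timelapse(
    spec: CellTimelapseSpec,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize the capsule per frame; return (stack, ground-truth table).

    The table has columns frame, cell_id, width_um, centroid_x_um,
    centroid_y_um.  Frames where the rasterized width would fall below two
    pixels are rejected as unresolvable.
    """
    h, w = spec.image_shape
    stack = np.zeros((spec.n_frames, h, w), dtype=np.uint8)
    rows = []
    path = np.asarray(spec.centroid_path, dtype=float)
    for f in range(spec.n_frames):
        width = float(spec.width_schedule[f])
        if width / spec.pixel_size < 2.0:
            raise ValueError(
                f"frame {f}: width {width} µm is below 2 pixels at "
                f"{spec.pixel_size} µm/px — unresolvable"
            )
        if spec.n_frames == 1:
            direction = (1.0, 0.0)
        elif f == 0:
            direction = tuple(path[1] - path[0])
        else:
            direction = tuple(path[f] - path[f - 1])
        if np.hypot(*direction) == 0:
            direction = (1.0, 0.0)
        stack[f] = _capsule_mask(
            tuple(path[f]), direction, spec.length, width,
            spec.pixel_size, spec.image_shape,
        )
        rows.append(
            dict(
                frame=f,
                cell_id=spec.cell_id,
                width_um=width,
                centroid_x_um=path[f, 0],
                centroid_y_um=path[f, 1],
            )
        )
    return stack, pd.DataFrame(rows)


def combine_label_stacks(stacks_truths: Sequence[tuple[np.ndarray, pd.DataFrame]]) -> tuple[np.ndarray, pd.DataFrame]:
    """Merge single-cell binary stacks into one label stack.

    Cell i (1-based) keeps label i; overlapping pixels go to the lower
    label (deterministic).  Ground-truth tables are concatenated with
    cell_id rewritten to the label.
    """
    if not stacks_truths:
        raise ValueError("no stacks to combine")
    shape = stacks_truths[0][0].shape
    labels = np.zeros(shape, dtype=np.int32)
    truths = []
    for i, (stack, truth) in enumerate(stacks_truths, start=1):
        if stack.shape != shape:
            raise ValueError("all stacks must share one shape")
        labels[(labels == 0) & (stack > 0)] = i
        t = truth.copy()
        t["cell_id"] = i
        truths.append(t)
    return labels, pd.concat(truths, ignore_index=True)


def straight_path(
    start: tuple[float, float],
    step_um: float,
    n_frames: int,
    direction: tuple[float, float] = (1.0, 0.0),
) -> list[tuple[float, float]]:
    """Constant-velocity centroid path: `step_um` per frame along `direction`."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return [
        (start[0] + step_um * f * d[0], start[1] + step_um * f * d[1])
        for f in range(n_frames)
    ]


# ---------------------------------------------------------------------------
# two-channel stainings


@dataclass(frozen=True)
class IntensitySpec:
    """Region means and noise for a simulated two-channel staining."""

    nuclear_mean: float
    cytosol_mean: float
    background_mean: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nuclear_mean", "cytosol_mean", "background_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


class TwoChannelImage(NamedTuple):
    """Simulated staining: a DNA channel (nucleus bright) and the reporter
    channel carrying the prescribed nuclear/cytosolic means."""

    dna: np.ndarray
    stain: np.ndarray


def make_two_channel_image(
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    spec: IntensitySpec,
) -> TwoChannelImage:
    """Draw pixels i.i.d. Gaussian around region means, clipped at zero.

    The reporter channel has ``nuclear_mean`` inside the nucleus,
    ``cytosol_mean`` in cell-minus-nucleus and ``background_mean`` outside
    the cell; the DNA channel is bright in the nucleus only.  Seeded and
    bit-reproducible.
    """
    nuc = np.asarray(nucleus_mask) > 0
    cell = np.asarray(cell_mask) > 0
    if nuc.shape != cell.shape:
        raise ValueError("nucleus and cell masks must share one shape")
    if np.any(nuc & ~cell):
        raise ValueError("nucleus mask is not contained in the cell mask")
    rng = np.random.default_rng(spec.seed)
    stain = np.full(cell.shape, spec.background_mean, dtype=float)
    stain[cell] = spec.cytosol_mean
    stain[nuc] = spec.nuclear_mean
    dna = np.full(cell.shape, spec.background_mean, dtype=float)
    dna[nuc] = max(spec.nuclear_mean, spec.cytosol_mean, 1.0) * 2.0
    if spec.noise_sd > 0:
        stain = stain + rng.normal(0.0, spec.noise_sd, size=stain.shape)
        dna = dna + rng.normal(0.0, spec.noise_sd, size=dna.shape)
    return TwoChannelImage(dna=np.clip(dna, 0, None), stain=np.clip(stain, 0, None))


# ---------------------------------------------------------------------------
# qPCR Ct tables


def make_ct_table(
    expression_ratios: Mapping[str, float],
    control_condition: str,
    n_replicates: int = 3,
    base_ct: float = 25.0,
    reference_ct: float = 18.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    target_gene: str = "Ccr7",
    reference_gene: str = "Gapdh",
) -> pd.DataFrame:
    """Simulate a long-form Ct table from known expression ratios.

    Each condition's target Ct is ``base_ct - log2(ratio) + noise`` (one
    extra cycle of target Ct halves apparent expression) and the reference
    gene sits at ``reference_ct + noise``.  The control condition must carry
    ratio 1 so folds are relative to it.

    Returns a DataFrame with columns (sample_id, condition, gene, ct).
    """
    if control_condition not in expression_ratios:
        raise ValueError("control condition missing from expression_ratios")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, ratio in expression_ratios.items():
        if ratio <= 0:
            raise ValueError("expression ratios must be > 0")
        for rep in range(n_replicates):
            sid = f"{cond}_r{rep + 1}"
            ct_t = base_ct - np.log2(ratio) + rng.normal(0.0, noise_sd)
            ct_r = reference_ct + rng.normal(0.0, noise_sd)
            for gene, ct in ((target_gene, ct_t), (reference_gene, ct_r)):
                if not (0.0 < ct < 45.0):
                    raise ValueError(f"simulated Ct {ct:.1f} outside (0, 45)")
                rows.append(
                    dict(sample_id=sid, condition=cond, gene=gene, ct=float(ct))
                )
    return pd.DataFrame(rows)
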