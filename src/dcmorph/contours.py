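"""Nuclear-envelope shape statistics from closed planar contours.

Two descriptors quantify how folded ("wrinkled") a nuclear envelope is in a
2D section:

* **EOP** (excess of perimeter): ``(P - 2*pi*R0) / (2*pi*R0)`` where ``P`` is
  the contour perimeter and ``R0`` the radius of the circle with the same
  enclosed area.  A circle scores 0; a heavily folded envelope approaches 1.
* **EFC ratio** (elliptic Fourier contribution ratio): the closed contour is
  expanded into a sum of harmonically rotating ellipses (Kuhl–Giardina
  elliptic Fourier descriptors).  The ratio of the first ellipse's
  major+minor axes to the summed axes of all higher harmonics measures how
  much of the shape is captured by a single smooth ellipse — larger means
  smoother, more regular.

Both statistics are invariant to translation, rotation and (for EOP and the
ratio) uniform scaling, and EOP is non-negative for every simple closed
curve by the isoperimetric inequality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import measure as _skmeasure

__all__ = [
    "Contour",
    "ShapeMetrics",
    "HarmonicSet",
    "EfcResult",
    "DEGENERATE_EFC_CAP",
    "mask_to_contour",
    "compute_eop",
    "elliptic_fourier_decompose",
    "compute_efc_ratio",
    "nucleus_projected_area",
    "shape_metrics",
    "resample_arclength",
]

#: Value reported in tables when the EFC denominator is numerically zero
#: (a perfect ellipse needs no higher harmonics).
DEGENERATE_EFC_CAP = 1.0e6

#: Denominator threshold, relative to the first-harmonic axes, below which
#: the EFC ratio is flagged degenerate.
_EFC_EPS = 1.0e-6

#: Number of equally spaced arc-length samples used before the Fourier
#: decomposition; fixed so results are deterministic.
_N_RESAMPLE = 1024


class ContourError(ValueError):
    """Raised for invalid contours or masks."""


@dataclass(frozen=True)
class Contour:
    """Closed simple planar curve in µm, counterclockwise, closure implied.

    The first vertex is not repeated at the end; consecutive duplicate
    vertices are removed on construction and orientation is normalised to
    counterclockwise (positive shoelace area).
    """

    vertices: np.ndarray  # (n, 2) float64, columns (x, y) in µm

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ContourError(f"vertices must be (n, 2), got {v.shape}")
        # drop consecutive duplicates (including wrap-around duplicate)
        keep = np.any(v != np.roll(v, 1, axis=0), axis=1)
        v = v[keep]
        if len(v) < 8:
            raise ContourError(
                f"contour needs >= 8 distinct vertices, got {len(v)}"
            )
        if _shoelace_area(v) < 0:
            v = v[::-1].copy()
        if _shoelace_area(v) <= 0:
            raise ContourError("contour encloses zero area")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def area(self) -> float:
        """Enclosed area (shoelace), µm²."""
        return _shoelace_area(self.vertices)

    @property
    def perimeter(self) -> float:
        """Summed segment lengths of the closed polyline, µm."""
        return _perimeter(self.vertices)

    def is_simple(self) -> bool:
        """True if the polygon does not self-intersect (shapely check)."""
        from shapely.geometry import LinearRing

        return LinearRing(self.vertices).is_simple

    def transformed(
        self,
        *,
        rotation: float = 0.0,
        scale: float = 1.0,
        translation: tuple[float, float] = (0.0, 0.0),
    ) -> "Contour":
        """Rigidly transform (rotate by `rotation` rad, scale, translate)."""
        c, s = np.cos(rotation), np.sin(rotation)
        R = np.array([[c, -s], [s, c]])
        v = scale * (self.vertices @ R.T) + np.asarray(translation, float)
        return Contour(v)


@dataclass(frozen=True)
class ShapeMetrics:
    """Per-nucleus shape summary."""

    area: float  # µm²
    perimeter: float  # µm
    r0: float  # radius of the equal-area circle, µm
    eop: float  # excess-of-perimeter, dimensionless, >= 0
    efc_ratio: Optional[float] = None
    efc_degenerate: Optional[bool] = None
    n_harmonics: Optional[int] = None


@dataclass(frozen=True)
class HarmonicSet:
    """Elliptic Fourier coefficients and per-harmonic ellipse axes.

    ``coeffs[k-1] = (a_k, b_k, c_k, d_k)`` are the cosine/sine coefficients
    of x(t) and y(t) for harmonic k; ``semi_major``/``semi_minor`` are the
    singular values of the 2x2 block ``[[a, b], [c, d]]`` — the semi-axes of
    the k-th Fourier ellipse, in µm.
    """

    coeffs: np.ndarray  # (N, 4)
    semi_major: np.ndarray  # (N,), A_k >= B_k >= 0
    semi_minor: np.ndarray  # (N,)

    @property
    def n_harmonics(self) -> int:
        return len(self.coeffs)


@dataclass(frozen=True)
class EfcResult:
    """EFC ratio with its degeneracy flag.

    ``value`` is capped at :data:`DEGENERATE_EFC_CAP` when ``degenerate``
    (the contour is a numerically perfect ellipse and the higher-harmonic
    denominator vanishes).
    """

    value: float
    degenerate: bool


# ---------------------------------------------------------------------------
# primitive geometry


def _shoelace_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _perimeter(v: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)))


def resample_arclength(v: np.ndarray, n: int = _N_RESAMPLE) -> np.ndarray:
    """Resample a closed polyline at `n` equally spaced arc-length points.

    The first output point coincides with the first input vertex, making the
    operation deterministic.
    """
    closed = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    s = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(s, t, closed[:, 0])
    y = np.interp(s, t, closed[:, 1])
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# mask -> contour


def mask_to_contour(mask: np.ndarray, pixel_size: float) -> Contour:
    """Extract the subpixel boundary of a single-object binary mask.

    The 0.5-level iso-contour of the mask is traced (marching squares), the
    largest closed curve kept, and coordinates scaled to µm with pixel
    centers at (index + 0.5) * pixel_size.

    Raises
    ------
    ContourError
        If the mask is empty, has more than one connected component, or the
        component touches the image border (its contour would be clipped).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    m = np.asarray(mask) > 0
    labels, n = _skmeasure.label(m, return_num=True, connectivity=2)
    if n != 1:
        raise ContourError(f"expected exactly 1 foreground component, found {n}")
    if int(m.sum()) < 16:
        raise ContourError("foreground component smaller than 16 pixels")
    border = np.concatenate([m[0], m[-1], m[:, 0], m[:, -1]])
    if border.any():
        raise ContourError("foreground component touches the image border")
    contours = _skmeasure.find_contours(m.astype(float), 0.5)
    if not contours:  # pragma: no cover - guarded by checks above
        raise ContourError("no iso-contour found")
    rc = max(contours, key=lambda c: abs(_shoelace_area(c[:, ::-1])))
    if not np.allclose(rc[0], rc[-1]):  # pragma: no cover
        raise ContourError("largest contour is not closed")
    rc = rc[:-1]
    # (row, col) index space -> (x, y) µm; find_contours places pixel
    # centers at integer indices, our physical centers sit at (i + 0.5) px.
    xy = np.column_stack([(rc[:, 1] + 0.5), (rc[:, 0] + 0.5)]) * pixel_size
    return Contour(xy)


# ---------------------------------------------------------------------------
# EOP


def compute_eop(contour: Contour) -> ShapeMetrics:
    """Excess-of-perimeter of a closed contour.

    area by shoelace, P by summed segment lengths, ``R0 = sqrt(area/pi)``,
    ``eop = (P - 2*pi*R0) / (2*pi*R0)``.  Zero only for a circle.
    """
    area = contour.area
    if area <= 0:  # Contour guarantees this, but guard for subclasses
        raise ContourError("contour area must be positive")
    per = contour.perimeter
    r0 = float(np.sqrt(area / np.pi))
    circ = 2.0 * np.pi * r0
    return ShapeMetrics(area=area, perimeter=per, r0=r0, eop=(per - circ) / circ)


# ---------------------------------------------------------------------------
# elliptic Fourier decomposition


def elliptic_fourier_decompose(
    contour: Contour, n_harmonics: int = 25
) -> HarmonicSet:
    """Kuhl–Giardina elliptic Fourier descriptors of a closed contour.

    The contour is resampled to 1,024 equally spaced arc-length points and
    the piecewise-linear closed-form integrals evaluated for harmonics
    1..n_harmonics.  Per-harmonic ellipse semi-axes are the singular values
    of the coefficient block ``[[a_k, b_k], [c_k, d_k]]``; they are invariant
    to translation, rotation, starting vertex and traversal direction.
    """
    if n_harmonics < 2:
        raise ValueError("n_harmonics must be >= 2 (EFC ratio undefined below)")
    v = resample_arclength(contour.vertices, _N_RESAMPLE)
    coeffs = _efd_coefficients(v, n_harmonics)
    a = coeffs.reshape(-1, 2, 2)
    s = np.linalg.svd(a, compute_uv=False)
    return HarmonicSet(coeffs=coeffs, semi_major=s[:, 0], semi_minor=s[:, 1])


def _efd_coefficients(v: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Closed-form EFD integrals for a closed polyline (vertices (n, 2))."""
    d = np.roll(v, -1, axis=0) - v
    dt = np.linalg.norm(d, axis=1)
    if np.any(dt == 0):
        raise ContourError("zero-length segment in contour")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    n = np.arange(1, n_harmonics + 1)[:, None]  # (N, 1)
    w = 2.0 * np.pi * n / T
    cos_t = np.cos(w * t)  # (N, n+1)
    sin_t = np.sin(w * t)
    dcos = cos_t[:, 1:] - cos_t[:, :-1]
    dsin = sin_t[:, 1:] - sin_t[:, :-1]
    k = T / (2.0 * (n[:, 0] ** 2) * np.pi**2)
    dxdt = d[:, 0] / dt
    dydt = d[:, 1] / dt
    a = k * (dcos @ dxdt)
    b = k * (dsin @ dxdt)
    c = k * (dcos @ dydt)
    dd = k * (dsin @ dydt)
    return np.column_stack([a, b, c, dd])


def efd_reconstruct(
    harmonics: HarmonicSet, contour: Contour, n_points: int = 512
) -> np.ndarray:
    """Reconstruct contour points from the harmonic series (plus centroid).

    Used to validate decomposition quality; the DC term is taken from the
    resampled source contour.
    """
    v = resample_arclength(contour.vertices, _N_RESAMPLE)
    d = np.roll(v, -1, axis=0) - v
    dt = np.linalg.norm(d, axis=1)
    T = dt.sum()
    # DC (centroid of the arc-length parameterization)
    tc = np.concatenate([[0.0], np.cumsum(dt)])[:-1] + dt / 2.0
    a0 = float(np.sum(v[:, 0] * dt) / T)
    c0 = float(np.sum(v[:, 1] * dt) / T)
    del tc
    t = np.linspace(0.0, T, n_points, endpoint=False)
    n = np.arange(1, harmonics.n_harmonics + 1)[:, None]
    arg = 2.0 * np.pi * n * t[None, :] / T
    cos_a, sin_a = np.cos(arg), np.sin(arg)
    a, b, c, dd = harmonics.coeffs.T
    x = a0 + a @ cos_a + b @ sin_a
    y = c0 + c @ cos_a + dd @ sin_a
    return np.column_stack([x, y])


def compute_efc_ratio(harmonics: HarmonicSet) -> EfcResult:
    """EFC ratio: first-ellipse axes over the summed axes of all others.

    ``(A1 + B1) / sum_{k>=2}(A_k + B_k)``.  When the denominator is below
    1e-6 of the numerator the contour is (numerically) a pure ellipse; the
    result is flagged degenerate and capped at :data:`DEGENERATE_EFC_CAP`.
    """
    if harmonics.n_harmonics < 2:
        raise ValueError("EFC ratio needs at least 2 harmonics")
    num = float(harmonics.semi_major[0] + harmonics.semi_minor[0])
    den = float(
        np.sum(harmonics.semi_major[1:]) + np.sum(harmonics.semi_minor[1:])
    )
    if den < _EFC_EPS * num:
        return EfcResult(value=DEGENERATE_EFC_CAP, degenerate=True)
    return EfcResult(value=num / den, degenerate=False)


# ---------------------------------------------------------------------------
# convenience


def nucleus_projected_area(mask: np.ndarray, pixel_size: float) -> float:
    """Projected nucleus area: foreground pixel count × pixel_size², µm²."""
    m = np.asarray(mask) > 0
    n = int(m.sum())
    if n == 0:
        raise ContourError("empty mask")
    labels, ncomp = _skmeasure.label(m, return_num=True, connectivity=2)
    if ncomp != 1:
        raise ContourError(f"expected exactly 1 component, found {ncomp}")
    return n * pixel_size**2


def shape_metrics(
    contour: Contour, n_harmonics: int = 25
) -> ShapeMetrics:
    """All shape statistics of one contour: area, P, R0, EOP and EFC ratio."""
    base = compute_eop(contour)
    efc = compute_efc_ratio(elliptic_fourier_decompose(contour, n_harmonics))
    return ShapeMetrics(
        area=base.area,
        perimeter=base.perimeter,
        r0=base.r0,
        eop=base.eop,
        efc_ratio=efc.value,
        efc_degenerate=efc.degenerate,
        n_harmonics=n_harmonics,
    )
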