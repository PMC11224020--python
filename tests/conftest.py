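"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dcmorph import Contour


def circle_vertices(radius: float = 5.0, n: int = 720, center=(0.0, 0.0)) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


def ellipse_vertices(a: float, b: float, n: int = 720) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(th), b * np.sin(th)])


def star_vertices(
    radius: float, amplitude: float, frequency: int, phase: float = 0.0, n: int = 720
) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = radius * (1.0 + amplitude * np.cos(frequency * th + phase))
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def efd_axes_oracle(vertices: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Independent elliptic-Fourier oracle: per-segment closed-form
    integrals evaluated directly on the given polygon (no resampling),
    ellipse axes by explicit eigendecomposition of M M^T rather than SVD.

    Returns an (N, 2) array of (semi_major, semi_minor) per harmonic.
    """
    v = np.asarray(vertices, dtype=float)
    d = np.roll(v, -1, axis=0) - v
    dt = np.linalg.norm(d, axis=1)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    axes = []
    for n in range(1, n_harmonics + 1):
        w = 2.0 * np.pi * n / T
        k = T / (2.0 * n**2 * np.pi**2)
        dc = np.cos(w * t[1:]) - np.cos(w * t[:-1])
        ds = np.sin(w * t[1:]) - np.sin(w * t[:-1])
        a = k * np.sum(dc * d[:, 0] / dt)
        b = k * np.sum(ds * d[:, 0] / dt)
        c = k * np.sum(dc * d[:, 1] / dt)
        dd = k * np.sum(ds * d[:, 1] / dt)
        m = np.array([[a, b], [c, dd]])
        eig = np.linalg.eigvalsh(m @ m.T)  # ascending, >= 0
        eig = np.clip(eig, 0.0, None)
        axes.append([np.sqrt(eig[1]), np.sqrt(eig[0])])
    return np.array(axes)


def disk_mask(radius_px: int, shape=(64, 64), center=None) -> np.ndarray:
    h, w = shape
    if center is None:
        center = (h / 2.0, w / 2.0)
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    return (
        ((jj + 0.5 - center[1]) ** 2 + (ii + 0.5 - center[0]) ** 2)
        <= radius_px**2
    ).astype(np.uint8)


@pytest.fixture
def circle_contour() -> Contour:
    return Contour(circle_vertices(5.0))


@pytest.fixture
def ellipse_contour() -> Contour:
    return Contour(ellipse_vertices(2.0, 1.0))
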