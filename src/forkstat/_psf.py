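"""Pixel-integrated 2D Gaussian PSF primitives shared by the simulator and the fitter.

Coordinate convention (used repo-wide): positions are continuous nanometres with
the origin at the outer corner of pixel (0, 0); pixel (i, j) spans
[j*a, (j+1)*a) x [i*a, (i+1)*a) nm for pixel size a, so the centre of pixel
(i, j) is at ((j+0.5)*a, (i+0.5)*a).  Image arrays are indexed [row, col] =
[y-pixel, x-pixel].
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def integrated_gaussian_1d(edges: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Fraction of a unit 1D Gaussian falling in each cell of ``edges``.

    ``edges`` has length n+1 for n cells; the result sums to <= 1 (tails
    outside the grid are lost, which is the physical photon loss at ROI
    borders).
    """
    z = (np.asarray(edges, dtype=float) - center) / (sigma * _SQRT2)
    c = 0.5 * erf(z)
    return c[1:] - c[:-1]


def integrated_gaussian_1d_deriv(edges: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """d/d(center) of :func:`integrated_gaussian_1d`."""
    z = (np.asarray(edges, dtype=float) - center) / sigma
    phi = _INV_SQRT_2PI * np.exp(-0.5 * z * z)
    return -(phi[1:] - phi[:-1]) / sigma


def render_psf(shape: tuple[int, int], x: float, y: float, sigma: float,
               pixel_size: float, photons: float = 1.0,
               origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Render one emitter as a pixel-integrated Gaussian on a grid.

    ``origin`` is the nm coordinate of the outer corner of array element
    (0, 0), so the same routine renders full frames and cropped ROIs.
    """
    ny, nx = shape
    x_edges = origin[0] + np.arange(nx + 1) * pixel_size
    y_edges = origin[1] + np.arange(ny + 1) * pixel_size
    ex = integrated_gaussian_1d(x_edges, x, sigma)
    ey = integrated_gaussian_1d(y_edges, y, sigma)
    return photons * np.outer(ey, ex)
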