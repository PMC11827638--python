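"""Pixel-integrated 2D Gaussian point-spread function.

Shared between the camera renderer and the spot fitter so that fitting is
consistent with image formation.  Pixel ``(row, col)`` covers the area
[col*p, (col+1)*p) x [row*p, (row+1)*p) in nm; its center is at
((col+0.5)*p, (row+0.5)*p).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["integrated_gaussian_1d", "spot_patch"]

_SQRT2 = np.sqrt(2.0)


def integrated_gaussian_1d(lo_nm, hi_nm, center_nm, sigma_nm):
    """Integral of a unit-area 1D Gaussian over [lo, hi]."""
    s = sigma_nm * _SQRT2
    return 0.5 * (erf((hi_nm - center_nm) / s) - erf((lo_nm - center_nm) / s))

def spot_patch(rows, cols, x_nm, y_nm, sigma_nm, pixel_nm):
    """Fraction of a spot's photons landing in each pixel of a grid.

    ``rows``/``cols`` are 1D integer pixel indices; returns an array of shape
    (len(rows), len(cols)) summing to <= 1 (exactly 1 over an infinite grid).
    """
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    gy = integrated_gaussian_1d(rows * pixel_nm, (rows + 1) * pixel_nm, y_nm, sigma_nm)
    gx = integrated_gaussian_1d(cols * pixel_nm, (cols + 1) * pixel_nm, x_nm, sigma_nm)
    return np.outer(gy, gx)
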