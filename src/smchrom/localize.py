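"""Single-molecule spot detection, sub-pixel Gaussian fitting and
super-resolution map reconstruction.

Detection runs a difference-of-Gaussians bandpass and picks local maxima
above a robust threshold; candidates are refined by least-squares fitting of
a pixel-integrated symmetric 2D Gaussian plus constant offset.  The
per-localization precision follows the Thompson-style formula

    var = (sigma^2 + p^2/12) / N + 8 pi sigma^4 b^2 / (p^2 N^2)

with p the pixel size, N the fitted photon count and b the fitted local
background (photons/pixel).  Localizations are binned into a 2D count
histogram (default 30-nm map pixels) for the super-resolution map.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

from .errors import DataError
from .psf import spot_patch

__all__ = [
    "LocalizeParams",
    "SRMap",
    "detect_spots",
    "fit_spot",
    "localize_movie",
    "reconstruct_map",
    "LOCALIZATION_COLUMNS",
]

# ThunderSTORM-compatible column ordering.
LOCALIZATION_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "photons",
    "sigma_nm",
    "background",
    "precision_nm",
]


@dataclass(frozen=True)
class LocalizeParams:
    """Tunable detection/fitting parameters.

    ``threshold_k`` scales the robust (MAD-based) SD added to the median of
    the bandpassed frame; ``sigma_window`` and ``n_min_photons`` are the
    acceptance gates on the fitted PSF width and photon count.
    """

    pixel_size_nm: float = 100.0
    psf_sigma_nm: float = 130.0
    threshold_k: float = 4.0
    min_separation_px: int = 4
    roi_half: int = 3
    n_min_photons: float = 100.0
    sigma_window: tuple[float, float] = (0.5, 2.0)
    dog_low_px: float = 1.0
    max_center_shift_px: float = 2.0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm


def detect_spots(frame: np.ndarray, params: LocalizeParams) -> np.ndarray:
    """Candidate spot positions in one frame.

    Returns an (n, 2) integer array of (row, col) local maxima of the
    difference-of-Gaussians filtered frame exceeding
    median + k * 1.4826 * MAD, separated by at least
    ``min_separation_px`` and clear of the ROI border.
    """
    img = np.asarray(frame, dtype=float)
    filt = difference_of_gaussians(
        img, low_sigma=params.dog_low_px, high_sigma=2.0 * params.psf_sigma_px
    )
    med = np.median(filt)
    mad = np.median(np.abs(filt - med))
    thr = med + params.threshold_k * 1.4826 * mad
    return peak_local_max(
        filt,
        min_distance=params.min_separation_px,
        threshold_abs=thr,
        exclude_border=params.roi_half,
    )


def _roi_model(pixel_nm, rows, cols):
    def model(_, n_photons, x0, y0, sigma, offset):
        patch = spot_patch(rows, cols, x0, y0, abs(sigma), pixel_nm)
        return (n_photons * patch + offset).ravel()

    return model


def fit_spot(frame: np.ndarray, peak_rc, params: LocalizeParams):
    """Least-squares Gaussian fit of one candidate.

    Returns ``(localization_dict, "ok")`` on success or ``(None, reason)``
    with reason one of ``edge``, ``no_converge``, ``off_center``,
    ``sigma_window``, ``low_photons``.  Coordinates are in nm in the global
    frame (pixel (r, c) center at ((c+0.5) p, (r+0.5) p)).
    """
    r0, c0 = int(peak_rc[0]), int(peak_rc[1])
    h = params.roi_half
    p = params.pixel_size_nm
    if (
        r0 - h < 0
        or c0 - h < 0
        or r0 + h >= frame.shape[0]
        or c0 + h >= frame.shape[1]
    ):
        return None, "edge"
    roi = np.asarray(frame[r0 - h : r0 + h + 1, c0 - h : c0 + h + 1], dtype=float)
    rows = np.arange(r0 - h, r0 + h + 1)
    cols = np.arange(c0 - h, c0 + h + 1)

    offset0 = float(np.median(roi))
    amp = roi - offset0
    n0 = max(float(amp.sum()), 10.0)
    x0 = (c0 + 0.5) * p
    y0 = (r0 + 0.5) * p
    sig0 = params.psf_sigma_nm
    # Unbounded Levenberg-Marquardt with a good initial guess is much faster
    # than a bounded solver; implausible optima are rejected by the windows
    # below.  |sigma| keeps the model well-defined on the whole real line.
    model = _roi_model(p, rows, cols)
    try:
        with warnings.catch_warnings():
            # singular covariance on degenerate (noise-only) ROIs is routine;
            # such fits fail the acceptance gates below anyway
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                model,
                np.zeros(roi.size),
                roi.ravel(),
                p0=[n0, x0, y0, sig0, max(offset0, 0.0)],
                method="lm",
                maxfev=300,
            )
    except (RuntimeError, ValueError):
        return None, "no_converge"
    n_phot, xf, yf, sigf, bg = popt
    sigf = abs(sigf)
    bg = max(bg, 0.0)
    if n_phot <= 0:
        return None, "low_photons"
    if np.hypot(xf - x0, yf - y0) > params.max_center_shift_px * p:
        return None, "off_center"
    s_lo, s_hi = params.sigma_window
    if not (s_lo * params.psf_sigma_nm <= sigf <= s_hi * params.psf_sigma_nm):
        return None, "sigma_window"
    if n_phot < params.n_min_photons:
        return None, "low_photons"
    var = (sigf**2 + p**2 / 12.0) / n_phot + (
        8.0 * np.pi * sigf**4 * bg**2 / (p**2 * n_phot**2)
    )
    return (
        {
            "x_nm": float(xf),
            "y_nm": float(yf),
            "photons": float(n_phot),
            "sigma_nm": float(sigf),
            "background": float(bg),
            "precision_nm": float(np.sqrt(var)),
        },
        "ok",
    )


def localize_movie(
    movie: np.ndarray, params: LocalizeParams | None = None
) -> pd.DataFrame:
    """Detect and fit spots in every frame of a movie stack.

    Returns a localization table with ThunderSTORM-compatible columns
    (frame, x_nm, y_nm, photons, sigma_nm, background, precision_nm); the
    per-reason rejection tally is attached as ``df.attrs["rejections"]``.
    """
    params = params or LocalizeParams()
    movie = np.asarray(movie)
    if movie.ndim == 2:
        movie = movie[None]
    rows = []
    rejections: Counter = Counter()
    for k in range(movie.shape[0]):
        for rc in detect_spots(movie[k], params):
            loc, reason = fit_spot(movie[k], rc, params)
            if loc is None:
                rejections[reason] += 1
            else:
                rows.append({"frame": k, **loc})
    df = pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)
    df["frame"] = df["frame"].astype(int) if len(df) else df["frame"]
    df.attrs["rejections"] = dict(rejections)
    return df


@dataclass
class SRMap:
    """Super-resolution reconstruction: 2D localization count histogram.

    ``counts[row, col]`` covers map pixel
    [origin + col*pixel, origin + (col+1)*pixel) in x and likewise in y.
    """

    counts: np.ndarray
    pixel_nm: float = 30.0
    origin_nm: tuple[float, float] = (0.0, 0.0)  # (x, y) of counts[0, 0] corner

    @property
    def n_localizations(self) -> int:
        return int(self.counts.sum())

    def pixel_centers(self):
        """(x, y) coordinate grids (nm) of the map pixel centers."""
        ny, nx = self.counts.shape
        x = self.origin_nm[0] + (np.arange(nx) + 0.5) * self.pixel_nm
        y = self.origin_nm[1] + (np.arange(ny) + 0.5) * self.pixel_nm
        return np.meshgrid(x, y)


def reconstruct_map(
    localizations: pd.DataFrame,
    map_pixel_nm: float = 30.0,
    extent_nm: tuple[float, float] | None = None,
    origin_nm: tuple[float, float] = (0.0, 0.0),
) -> SRMap:
    """Bin localizations into a super-resolution count map.

    ``extent_nm`` is the (height, width) covered by the map starting at
    ``origin_nm``; by default it is taken from the data.  The map conserves
    the localization count exactly (out-of-extent points raise).
    """
    if len(localizations) == 0:
        raise DataError("cannot reconstruct a map from zero localizations")
    x = localizations["x_nm"].to_numpy(dtype=float)
    y = localizations["y_nm"].to_numpy(dtype=float)
    if extent_nm is None:
        extent_nm = (
            float(np.max(y) - origin_nm[1]) + map_pixel_nm,
            float(np.max(x) - origin_nm[0]) + map_pixel_nm,
        )
    ny = int(np.ceil(extent_nm[0] / map_pixel_nm))
    nx = int(np.ceil(extent_nm[1] / map_pixel_nm))
    col = np.floor((x - origin_nm[0]) / map_pixel_nm).astype(int)
    row = np.floor((y - origin_nm[1]) / map_pixel_nm).astype(int)
    if np.any((col < 0) | (col >= nx) | (row < 0) | (row >= ny)):
        raise DataError("localizations fall outside the requested map extent")
    counts = np.zeros((ny, nx), dtype=np.int64)
    np.add.at(counts, (row, col), 1)
    return SRMap(counts=counts, pixel_nm=map_pixel_nm, origin_nm=origin_nm)
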