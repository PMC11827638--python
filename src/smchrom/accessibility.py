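"""Pore-accessibility metrics from super-resolution maps.

Quantifies how deep analytes penetrate a particle cross-section:

* ``fit_outline`` — ellipse fitted (via second-order image moments) to the
  binarized, morphologically closed super-resolution map; defines the imaged
  cross-sectional area A_i = pi a b and the particle radius r = (a + b)/2.
* ``compute_depths`` — per-localization depth from the outer edge in %r,
  using the normalized elliptical radius so %r is exact even for eccentric
  outlines; d99 is the 99th percentile of depth, i.e. the accessible-depth
  limit beyond which 99% of analytes do not reach.
* ``accessible_area`` — A_p, the map area covered by localizations (after
  the same closing) inside the ellipse, and the accessibility ratio A_p/A_i.
* ``aggregate_particles`` — mean +/- SD of the metrics and of the depth CDF
  across particles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label
from skimage.morphology import closing as _gray_closing, disk

from .errors import DataError
from .geometry import normalized_radius
from .localize import SRMap, reconstruct_map

__all__ = [
    "ParticleOutline",
    "DepthDistribution",
    "AccessibilityResult",
    "fit_outline",
    "compute_depths",
    "accessible_area",
    "aggregate_particles",
    "assess_accessibility",
    "default_depth_grid",
]


@dataclass(frozen=True)
class ParticleOutline:
    """Fitted elliptical particle cross-section (nm)."""

    center_xy: tuple[float, float]
    a_nm: float
    b_nm: float
    tilt_rad: float

    def __post_init__(self):
        if not (self.a_nm >= self.b_nm > 0):
            raise ValueError(f"need a >= b > 0, got a={self.a_nm}, b={self.b_nm}")

    @property
    def area_um2(self) -> float:
        """Imaged cross-sectional area A_i = pi a b, in um^2."""
        return np.pi * self.a_nm * self.b_nm / 1e6

    @property
    def radius_nm(self) -> float:
        """Scalar particle radius r = (a + b)/2."""
        return 0.5 * (self.a_nm + self.b_nm)

    def rho(self, x_nm, y_nm) -> np.ndarray:
        return normalized_radius(
            x_nm, y_nm, self.center_xy, self.a_nm, self.b_nm, self.tilt_rad
        )


@dataclass
class DepthDistribution:
    """Per-localization depths from the particle edge, in %r."""

    depths_percent_r: np.ndarray
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return len(self.depths_percent_r)

    @property
    def d99_percent_r(self) -> float:
        """Accessible-depth limit: 99th percentile of depth (linear interp)."""
        return float(np.percentile(self.depths_percent_r, 99.0))

    def cdf(self, grid_percent_r: np.ndarray) -> np.ndarray:
        """Empirical depth CDF evaluated on a %r grid."""
        d = np.sort(self.depths_percent_r)
        return np.searchsorted(d, grid_percent_r, side="right") / len(d)


@dataclass
class AccessibilityResult:
    """Accessibility metrics of one particle."""

    outline: ParticleOutline
    d99_percent_r: float
    Ap_um2: float
    Ai_um2: float
    ratio: float
    n_localizations: int
    n_excluded: int
    cdf_grid_percent_r: np.ndarray
    cdf: np.ndarray

    def to_dict(self) -> dict:
        return {
            "d99_percent_r": self.d99_percent_r,
            "Ap_um2": self.Ap_um2,
            "Ai_um2": self.Ai_um2,
            "ratio": self.ratio,
            "r_nm": self.outline.radius_nm,
            "n_loc": self.n_localizations,
            "excluded": self.n_excluded,
        }


def default_depth_grid(step_percent_r: float = 0.5) -> np.ndarray:
    return np.arange(0.0, 100.0 + step_percent_r, step_percent_r)


def _closed_mask(srmap: SRMap, closing_radius_px: int) -> np.ndarray:
    mask = srmap.counts >= 1
    if closing_radius_px > 0:
        mask = _gray_closing(mask, disk(closing_radius_px)).astype(bool)
    return mask


def fit_outline(
    srmap: SRMap,
    min_localizations: int = 500,
    closing_radius_px: int = 3,
    min_component_px: int = 50,
) -> ParticleOutline:
    """Fit an ellipse to the binarized super-resolution map.

    Binarize (count >= 1), close with a disc (bridging gaps between discrete
    adsorption sites), keep the largest connected component, fill holes
    (so a hollow shell still yields the outer outline), then compute the
    ellipse from second-order image moments of the filled component: for a
    uniform filled ellipse the principal variances are a^2/4 and b^2/4.
    """
    if srmap.n_localizations < min_localizations:
        raise DataError(
            f"map holds {srmap.n_localizations} localizations; "
            f"need >= {min_localizations} to fit an outline"
        )
    mask = _closed_mask(srmap, closing_radius_px)
    lbl = label(mask)
    if lbl.max() == 0:
        raise DataError("no connected component found in binarized map")
    sizes = np.bincount(lbl.ravel())[1:]
    if sizes.max() < min_component_px:
        raise DataError(
            f"largest component has {sizes.max()} px; need >= {min_component_px}"
        )
    comp = lbl == (1 + int(np.argmax(sizes)))
    comp = ndimage.binary_fill_holes(comp)

    row, col = np.nonzero(comp)
    x = srmap.origin_nm[0] + (col + 0.5) * srmap.pixel_nm
    y = srmap.origin_nm[1] + (row + 0.5) * srmap.pixel_nm
    cx, cy = float(np.mean(x)), float(np.mean(y))
    cov = np.cov(np.vstack([x - cx, y - cy]), ddof=0)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    b_nm = 2.0 * np.sqrt(max(evals[0], 0.0))
    a_nm = 2.0 * np.sqrt(max(evals[1], 0.0))
    vx, vy = evecs[:, 1]
    tilt = np.arctan2(vy, vx)
    if tilt <= -np.pi / 2:
        tilt += np.pi
    elif tilt > np.pi / 2:
        tilt -= np.pi
    return ParticleOutline(center_xy=(cx, cy), a_nm=a_nm, b_nm=b_nm, tilt_rad=tilt)


def compute_depths(
    localizations,
    outline: ParticleOutline,
    outlier_tol: float = 0.05,
) -> DepthDistribution:
    """Depth of each localization from the particle edge, in %r.

    rho is the normalized elliptical radius; depth = (1 - min(rho, 1)) x 100.
    Localizations with rho > 1 + outlier_tol (localization noise outside the
    contour) are excluded and counted.
    """
    if isinstance(localizations, pd.DataFrame):
        x = localizations["x_nm"].to_numpy(dtype=float)
        y = localizations["y_nm"].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in localizations)
    if x.size == 0:
        raise DataError("cannot compute depths of zero localizations")
    rho = outline.rho(x, y)
    keep = rho <= 1.0 + outlier_tol
    depths = (1.0 - np.minimum(rho[keep], 1.0)) * 100.0
    if depths.size == 0:
        raise DataError("all localizations lie outside the outline")
    return DepthDistribution(
        depths_percent_r=depths, n_excluded=int((~keep).sum())
    )


def accessible_area(
    srmap: SRMap, outline: ParticleOutline, closing_radius_px: int = 3
):
    """Analyte-probed area A_p and the accessibility ratio A_p/A_i.

    A_p counts map pixels covered by localizations (after the same
    morphological closing used for the outline — holes are *not* filled, so
    an inaccessible core is not credited) whose centers lie inside the
    ellipse, times the map pixel area.
    """
    mask = _closed_mask(srmap, closing_radius_px)
    gx, gy = srmap.pixel_centers()
    inside = outline.rho(gx, gy) <= 1.0
    Ap_um2 = float(np.sum(mask & inside)) * (srmap.pixel_nm / 1e3) ** 2
    Ai_um2 = outline.area_um2
    ratio = min(Ap_um2 / Ai_um2, 1.0)
    return Ap_um2, ratio


def assess_accessibility(
    localizations: pd.DataFrame,
    map_pixel_nm: float = 30.0,
    closing_radius_px: int = 3,
    min_localizations: int = 500,
    outlier_tol: float = 0.05,
    extent_nm: tuple[float, float] | None = None,
    cdf_grid: np.ndarray | None = None,
) -> AccessibilityResult:
    """Full per-particle accessibility analysis from a localization table."""
    srmap = reconstruct_map(localizations, map_pixel_nm=map_pixel_nm, extent_nm=extent_nm)
    outline = fit_outline(
        srmap, min_localizations=min_localizations, closing_radius_px=closing_radius_px
    )
    dist = compute_depths(localizations, outline, outlier_tol=outlier_tol)
    Ap, ratio = accessible_area(srmap, outline, closing_radius_px=closing_radius_px)
    grid = default_depth_grid() if cdf_grid is None else np.asarray(cdf_grid, float)
    return AccessibilityResult(
        outline=outline,
        d99_percent_r=dist.d99_percent_r,
        Ap_um2=Ap,
        Ai_um2=outline.area_um2,
        ratio=ratio,
        n_localizations=dist.n,
        n_excluded=dist.n_excluded,
        cdf_grid_percent_r=grid,
        cdf=dist.cdf(grid),
    )


def aggregate_particles(results: list[AccessibilityResult]) -> dict:
    """Mean +/- sample SD of d99, A_p/A_i and the depth CDF over particles.

    All results must share the same %r CDF grid.  SD uses ddof=1 (sample SD,
    as quoted for particle-to-particle variability).
    """
    if len(results) < 2:
        raise DataError("aggregation needs >= 2 particles")
    grid = results[0].cdf_grid_percent_r
    for r in results[1:]:
        if not np.array_equal(r.cdf_grid_percent_r, grid):
            raise DataError("mismatched depth-CDF bin grids across particles")
    cdfs = np.vstack([r.cdf for r in results])
    d99 = np.array([r.d99_percent_r for r in results])
    ratio = np.array([r.ratio for r in results])
    return {
        "grid_percent_r": grid,
        "cdf_mean": cdfs.mean(axis=0),
        "cdf_sd": cdfs.std(axis=0, ddof=1),
        "d99_mean": float(d99.mean()),
        "d99_sd": float(d99.std(ddof=1)),
        "ratio_mean": float(ratio.mean()),
        "ratio_sd": float(ratio.std(ddof=1)),
        "n_particles": len(results),
        "n_localizations": int(sum(r.n_localizations for r in results)),
    }
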