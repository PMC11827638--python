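"""Elliptical particle cross-section geometry.

The particle outline is an ellipse with semi-axes ``a >= b`` tilted by
``tilt`` radians.  Positions are expressed through the normalized elliptical
radius rho = sqrt((x'/a)^2 + (y'/b)^2) in the ellipse's principal frame;
rho = 1 is the outer edge, rho = 0 the center.  Depth from the edge is
(1 - rho) and is quoted as a percent of the particle radius (%r).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalized_radius",
    "annulus_area_fraction",
    "annulus_d99",
    "uniform_disc_d99",
    "core_shell_geometry",
    "equivalent_layer_um",
]


def normalized_radius(x_nm, y_nm, center_xy, a_nm, b_nm, tilt_rad=0.0):
    """Normalized elliptical radius rho of points relative to an outline.

    Parameters are in nm; ``tilt_rad`` rotates the major axis counter-
    clockwise from the +x axis.  Returns an array with rho = 0 at the
    center and rho = 1 on the ellipse.
    """
    x = np.asarray(x_nm, dtype=float) - center_xy[0]
    y = np.asarray(y_nm, dtype=float) - center_xy[1]
    c, s = np.cos(tilt_rad), np.sin(tilt_rad)
    xp = c * x + s * y
    yp = -s * x + c * y
    return np.hypot(xp / a_nm, yp / b_nm)


def annulus_area_fraction(f: float) -> float:
    """Area of the accessible shell rho in [1-f, 1] relative to the full ellipse.

    Equals 1 - (1 - f)^2; f = 1 is a fully accessible cross-section.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError(f"accessible fraction must be in (0, 1], got {f}")
    return 1.0 - (1.0 - f) ** 2


def annulus_d99(f: float, q: float = 0.99) -> float:
    """Depth (in %r) within which a fraction ``q`` of uniformly distributed
    analytes in the shell rho in [1-f, 1] lie.

    For uniform sampling of the elliptical annulus the depth CDF is
    F(u) = (1 - (1-u)^2) / (1 - (1-f)^2) for u in [0, f] (u = depth / r), so
    the q-quantile is 100 * (1 - sqrt(1 - q * (1 - (1-f)^2))).
    """
    frac = annulus_area_fraction(f)
    return 100.0 * (1.0 - np.sqrt(1.0 - q * frac))


def uniform_disc_d99(q: float = 0.99) -> float:
    """Depth quantile (in %r) for a uniformly sampled full disc (f = 1)."""
    return annulus_d99(1.0, q)


def core_shell_geometry(core_diameter_um: float, shell_um: float):
    """Outer radius and accessible depth fraction of a core-shell particle.

    A superficially porous particle with a solid core of the given diameter
    and a porous shell of the given thickness has outer radius
    core/2 + shell and a geometrically accessible depth fraction
    shell / outer_radius (e.g. a 1.7-um core with a 0.5-um shell gives a
    1.35-um radius and ~37% of r accessible).
    """
    if core_diameter_um < 0 or shell_um <= 0:
        raise ValueError("core diameter must be >= 0 and shell thickness > 0")
    outer_radius_um = core_diameter_um / 2.0 + shell_um
    return outer_radius_um, shell_um / outer_radius_um


def equivalent_layer_um(depth_limit_percent_r: float, radius_um: float) -> float:
    """Convert an accessible-depth limit in %r to a layer thickness in um."""
    return depth_limit_percent_r / 100.0 * radius_um
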