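"""Quick-look figures: super-resolution maps, depth CDFs, elution peaks."""

from __future__ import annotations

import numpy as np


def plot_srmap(srmap, ax=None, outline=None, cmap="hot"):
    """Show a super-resolution count map (log-scaled) with an optional
    fitted ellipse overlay."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots()
    ny, nx = srmap.counts.shape
    extent = (
        srmap.origin_nm[0] / 1e3,
        (srmap.origin_nm[0] + nx * srmap.pixel_nm) / 1e3,
        (srmap.origin_nm[1] + ny * srmap.pixel_nm) / 1e3,
        srmap.origin_nm[1] / 1e3,
    )
    ax.imshow(np.log1p(srmap.counts), extent=extent, cmap=cmap)
    if outline is not None:
        ax.add_patch(
            Ellipse(
                (outline.center_xy[0] / 1e3, outline.center_xy[1] / 1e3),
                2 * outline.a_nm / 1e3,
                2 * outline.b_nm / 1e3,
                angle=np.degrees(outline.tilt_rad),
                fill=False,
                edgecolor="cyan",
            )
        )
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    return ax


def plot_depth_cdf(aggregate, ax=None, label=None, color=None):
    """Mean depth CDF with an SD band, as returned by aggregate_particles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    g = aggregate["grid_percent_r"]
    m = aggregate["cdf_mean"]
    s = aggregate["cdf_sd"]
    (line,) = ax.plot(g, m, label=label, color=color)
    ax.fill_between(g, m - s, m + s, alpha=0.3, color=line.get_color())
    ax.set_xlabel("distance from edge (%r)")
    ax.set_ylabel("cumulative fraction")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 1.02)
    if label:
        ax.legend()
    return ax


def plot_elution(profiles, ax=None):
    """Overlay modeled elution profiles; ``profiles`` maps label -> profile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, prof in profiles.items():
        ax.plot(prof.time_s, prof.density, label=label)
    ax.set_xlabel("elution time (s)")
    ax.set_ylabel("density (1/s)")
    ax.legend()
    return ax
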