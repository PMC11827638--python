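"""Adsorption-event construction and dwell-time kinetics.

Localizations are linked across consecutive frames into adsorption events
by greedy nearest-neighbor association; an event's dwell time is
t_D = n_frames x frame interval (n_frames is the frame span including
tolerated blink gaps).  Events touching the first or last movie frame are
flagged censored and excluded from rate estimates by default.

Desorption rates: the field's headline convention is k_d = 1/t_D (per-site,
``cluster_sites``).  Because the frame-span dwell of an event with true
duration tau and uniform start phase spans on average tau/dt + 1 frames,
the measured mean dwell overestimates tau by exactly one frame interval;
``desorption_rate`` removes that bias when estimating a rate from a dwell
sample.

Per-site adsorption free energies use a pseudo-first-order equilibrium
constant K_eq = k_a / (k_d * C/C0) with C0 = 1 M and
dG = -R T ln K_eq (kJ/mol).  The absolute offset of dG depends on this
reference-state convention; differences between sites do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import DataError

__all__ = [
    "EVENT_COLUMNS",
    "SITE_COLUMNS",
    "DwellTimeSet",
    "link_events",
    "dwell_distribution",
    "desorption_rate",
    "cluster_sites",
    "site_energetics",
    "equilibrium_free_energy",
]

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ / (mol K)

EVENT_COLUMNS = [
    "start_frame",
    "n_frames",
    "n_localizations",
    "dwell_s",
    "x_nm",
    "y_nm",
    "censored_start",
    "censored_end",
]
SITE_COLUMNS = ["x_nm", "y_nm", "n_events", "kd_per_s", "ka_per_s", "dG_kJ_mol"]


def link_events(
    localizations: pd.DataFrame,
    r_link_nm: float = 100.0,
    max_gap: int = 1,
    frame_interval_s: float = 0.032,
    n_frames: int | None = None,
) -> pd.DataFrame:
    """Link localizations across frames into adsorption events.

    Greedy nearest-neighbor association: in each frame, (track, candidate)
    pairs within ``r_link_nm`` are committed in order of increasing
    distance; a track survives up to ``max_gap`` consecutive missed frames
    (single-frame blinks by default).  Unmatched localizations seed new
    events.

    Returns an event table (one row per event) with the mean position of
    its member localizations, dwell_s = n_frames x frame interval where
    n_frames is the frame span (gap fills included; the localization count
    is reported separately), and censoring flags for events touching the
    first or the last movie frame.
    """
    df = localizations.sort_values("frame", kind="stable")
    frames = df["frame"].to_numpy(dtype=int)
    xs = df["x_nm"].to_numpy(dtype=float)
    ys = df["y_nm"].to_numpy(dtype=float)
    last_frame_idx = (
        (int(frames.max()) if len(frames) else 0) if n_frames is None else n_frames - 1
    )

    active: list[dict] = []
    closed: list[dict] = []

    for f in np.unique(frames):
        still_active = []
        for tr in active:
            if f - tr["end"] > max_gap + 1:
                closed.append(tr)
            else:
                still_active.append(tr)
        active = still_active

        idx = np.nonzero(frames == f)[0]
        if len(active) and len(idx):
            tx = np.array([tr["x"][-1] for tr in active])
            ty = np.array([tr["y"][-1] for tr in active])
            d = np.hypot(tx[:, None] - xs[idx][None, :], ty[:, None] - ys[idx][None, :])
            pairs = np.argwhere(d <= r_link_nm)
            order = np.argsort(d[pairs[:, 0], pairs[:, 1]]) if len(pairs) else []
            used_tr: set[int] = set()
            used_loc: set[int] = set()
            assigned = np.zeros(len(idx), dtype=bool)
            for ti, li in pairs[order] if len(pairs) else []:
                if ti in used_tr or li in used_loc:
                    continue
                used_tr.add(int(ti))
                used_loc.add(int(li))
                tr = active[ti]
                j = idx[li]
                tr["x"].append(xs[j])
                tr["y"].append(ys[j])
                tr["end"] = int(f)
                tr["n_loc"] += 1
                assigned[li] = True
        else:
            assigned = np.zeros(len(idx), dtype=bool)

        for li, j in enumerate(idx):
            if not assigned[li]:
                active.append(
                    {
                        "start": int(f),
                        "end": int(f),
                        "x": [xs[j]],
                        "y": [ys[j]],
                        "n_loc": 1,
                    }
                )
    closed.extend(active)

    rows = []
    for tr in closed:
        span = tr["end"] - tr["start"] + 1
        rows.append(
            {
                "start_frame": tr["start"],
                "n_frames": span,
                "n_localizations": tr["n_loc"],
                "dwell_s": span * frame_interval_s,
                "x_nm": float(np.mean(tr["x"])),
                "y_nm": float(np.mean(tr["y"])),
                "censored_start": tr["start"] == 0,
                "censored_end": tr["end"] >= last_frame_idx,
            }
        )
    ev = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return ev.sort_values(["start_frame", "x_nm"], ignore_index=True)


@dataclass
class DwellTimeSet:
    """Dwell-time sample at a fixed frame interval."""

    dwells_s: np.ndarray
    frame_interval_s: float = 0.032
    n_censored: int = 0

    @property
    def n(self) -> int:
        return len(self.dwells_s)

    @property
    def mean_s(self) -> float:
        return float(np.mean(self.dwells_s))

    def ecdf(self):
        """(sorted dwell values, cumulative fractions reaching 1)."""
        x = np.sort(self.dwells_s)
        return x, np.arange(1, len(x) + 1) / len(x)


def dwell_distribution(
    events: pd.DataFrame,
    exclude_censored: bool = True,
    frame_interval_s: float = 0.032,
) -> DwellTimeSet:
    """Pooled dwell-time set of linked events.

    Censored events (touching the movie boundaries, dwell truncated) are
    excluded by default; their count is retained.
    """
    if len(events) == 0:
        raise DataError("no events to build a dwell distribution from")
    cens = (
        events["censored_start"].to_numpy(bool) | events["censored_end"].to_numpy(bool)
        if exclude_censored
        else np.zeros(len(events), dtype=bool)
    )
    dwells = events.loc[~cens, "dwell_s"].to_numpy(dtype=float)
    if dwells.size == 0:
        raise DataError("all events are censored; no uncensored dwells")
    return DwellTimeSet(
        dwells_s=dwells,
        frame_interval_s=frame_interval_s,
        n_censored=int(cens.sum()),
    )


def desorption_rate(dwells_s, frame_interval_s: float) -> float:
    """Discretization-corrected desorption rate from a dwell sample.

    The frame-span dwell n*dt of an event of true duration tau with a
    uniform start phase has E[n*dt] = tau + dt, so the rate estimate uses
    1 / (mean dwell - dt), floored at half a frame to stay finite.
    """
    dwells_s = np.asarray(dwells_s, dtype=float)
    if dwells_s.size == 0:
        raise DataError("empty dwell sample")
    mean_corr = max(float(dwells_s.mean()) - frame_interval_s, frame_interval_s / 2.0)
    return 1.0 / mean_corr


def cluster_sites(
    events: pd.DataFrame,
    site_radius_nm: float = 60.0,
    duration_s: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Group events into adsorption sites and summarize per-site kinetics.

    Single-linkage clustering at ``site_radius_nm``: events whose positions
    can be chained by steps <= the radius share a site (connected components
    of the radius graph).  Per site, k_d = 1 / (mean uncensored dwell) and
    k_a = events / acquisition duration.  Sites whose events are all
    censored get k_d = NaN.

    Returns ``(sites, labels)`` where ``labels[i]`` is the site index of
    event i.
    """
    if len(events) == 0:
        raise DataError("no events to cluster")
    if duration_s is None or duration_s <= 0:
        raise DataError("a positive acquisition duration_s is required")
    pos = events[["x_nm", "y_nm"]].to_numpy(dtype=float)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(site_radius_nm, output_type="ndarray")
    n = len(pos)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)

    cens = events["censored_start"].to_numpy(bool) | events["censored_end"].to_numpy(
        bool
    )
    dwell = events["dwell_s"].to_numpy(dtype=float)
    rows = []
    for s in range(labels.max() + 1):
        m = labels == s
        unc = m & ~cens
        mean_dwell = float(dwell[unc].mean()) if unc.any() else np.nan
        rows.append(
            {
                "x_nm": float(pos[m, 0].mean()),
                "y_nm": float(pos[m, 1].mean()),
                "n_events": int(m.sum()),
                "kd_per_s": 1.0 / mean_dwell if np.isfinite(mean_dwell) else np.nan,
                "ka_per_s": float(m.sum()) / duration_s,
                "dG_kJ_mol": np.nan,  # filled by site_energetics
            }
        )
    return pd.DataFrame(rows, columns=SITE_COLUMNS), labels


def site_energetics(
    sites: pd.DataFrame,
    concentration_M: float = 1e-9,
    temperature_K: float = 298.15,
) -> pd.DataFrame:
    """Per-site adsorption free energy dG = -R T ln K_eq, in kJ/mol.

    K_eq = k_a / (k_d * C/C0) with the analyte concentration C and the 1 M
    reference state C0.  Returns a copy of ``sites`` with dG_kJ_mol filled
    (NaN where k_d or k_a is unavailable).
    """
    if concentration_M <= 0 or temperature_K <= 0:
        raise DataError("concentration and temperature must be positive")
    out = sites.copy()
    kd = out["kd_per_s"].to_numpy(dtype=float)
    ka = out["ka_per_s"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        keq = ka / (kd * concentration_M)
        dg = -GAS_CONSTANT_KJ * temperature_K * np.log(keq)
    out["dG_kJ_mol"] = np.where(np.isfinite(dg), dg, np.nan)
    return out


def equilibrium_free_energy(
    k_eq: float, temperature_K: float = 298.15
) -> float:
    """dG (kJ/mol) of a dimensionless equilibrium constant."""
    if k_eq <= 0:
        raise DataError("K_eq must be positive")
    return -GAS_CONSTANT_KJ * temperature_K * float(np.log(k_eq))
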