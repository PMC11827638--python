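"""Ground-truth simulator for single-molecule adsorption imaging.

Emulates the statistical structure the downstream analysis assumes:

* adsorption sites scattered as a spatial Poisson process over the
  accessible shell of an elliptical particle cross-section,
* per-site first-order (exponential) desorption, with between-site
  heterogeneity described by an n-site mixture of rate classes,
* Poisson arrivals of analyte at each site (nanomolar solution, so
  arrivals are non-blocking and a site may host overlapping events),
* diffraction-limited Gaussian spots recorded by a photon-counting
  camera with Poisson shot noise and Gaussian read noise, under a
  Gaussian light-sheet axial intensity envelope.

Each simulated acquisition is one 2D optical slice; 3D maps are obtained
by stacking independently simulated slices.  Freely diffusing analyte is
not rendered explicitly — at 32-ms exposures it blurs into the
``background`` parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import annulus_area_fraction, normalized_radius
from .psf import spot_patch

__all__ = [
    "ParticleSpec",
    "KineticMixture",
    "SiteMap",
    "ImagingSpec",
    "generate_site_map",
    "sample_accessible",
    "simulate_events",
    "truth_localizations",
    "render_movie",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = ["event_id", "site_id", "x_nm", "y_nm", "t_start_s", "dwell_s"]


@dataclass(frozen=True)
class ParticleSpec:
    """Geometry of one particle cross-section and its adsorption-site budget.

    ``accessible_fraction`` is the depth of the analyte-accessible shell as a
    fraction of the (elliptical) radius: 1.0 means the whole cross-section is
    reachable (bare fully porous silica), 0.37 reproduces a superficially
    porous particle with a 0.5-um shell on a 1.35-um radius.
    ``site_density`` is in adsorption sites per um^2 of accessible area.
    """

    center_xy: tuple[float, float] = (3200.0, 3200.0)
    a_nm: float = 2500.0
    b_nm: float = 2500.0
    tilt_rad: float = 0.0
    accessible_fraction: float = 1.0
    site_density_per_um2: float = 300.0

    def __post_init__(self):
        if not (self.a_nm >= self.b_nm > 0):
            raise ValueError(f"need a >= b > 0, got a={self.a_nm}, b={self.b_nm}")
        if not (0.0 < self.accessible_fraction <= 1.0):
            raise ValueError(
                f"accessible_fraction must be in (0, 1], got {self.accessible_fraction}"
            )
        if self.site_density_per_um2 < 0:
            raise ValueError("site_density_per_um2 must be >= 0")

    @property
    def radius_nm(self) -> float:
        """Scalar particle radius, reported as (a + b) / 2."""
        return 0.5 * (self.a_nm + self.b_nm)

    @property
    def area_um2(self) -> float:
        """Full cross-sectional area pi*a*b in um^2."""
        return np.pi * self.a_nm * self.b_nm / 1e6

    @property
    def accessible_area_um2(self) -> float:
        """Area of the accessible annulus rho in [1-f, 1] in um^2."""
        return self.area_um2 * annulus_area_fraction(self.accessible_fraction)

    def rho(self, x_nm, y_nm):
        return normalized_radius(
            x_nm, y_nm, self.center_xy, self.a_nm, self.b_nm, self.tilt_rad
        )


@dataclass(frozen=True)
class KineticMixture:
    """n-site kinetic heterogeneity: mixture of first-order site classes.

    Each component is ``(weight, k_d, k_a)`` — the fraction of sites in the
    class, the desorption rate (1/s; mean dwell 1/k_d) and the analyte
    arrival rate per site (events/s at the working concentration).
    """

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        comps = tuple((float(w), float(kd), float(ka)) for w, kd, ka in self.components)
        object.__setattr__(self, "components", comps)
        w = self.weights
        if len(comps) == 0:
            raise ValueError("mixture needs at least one component")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError(f"component weights must sum to 1, got {w.sum()}")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(self.k_d <= 0):
            raise ValueError("all k_d must be > 0")
        if np.any(self.k_a < 0):
            raise ValueError("all k_a must be >= 0")

    @classmethod
    def default(cls) -> "KineticMixture":
        """Three site classes spanning weak to strong adsorption at ~1 nM.

        Mean dwells 0.04, 0.125 and 0.5 s against a 32-ms frame (pooled mean
        0.139 s): most sojourns last a few frames, with a long-dwell minority
        that dominates peak tailing.  Per-site arrival rates are low enough
        that a dense site population still yields only a few simultaneously
        active molecules per frame — the sparsity single-molecule
        localization requires.
        """
        return cls(((0.5, 25.0, 0.0055), (0.35, 8.0, 0.0055), (0.15, 2.0, 0.0055)))

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def k_d(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def k_a(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])

    @property
    def mean_dwell_s(self) -> float:
        """Pooled expected dwell  sum_i w_i / k_d,i  (sites drawn i.i.d.)."""
        return float(np.sum(self.weights / self.k_d))

    def dwell_cdf(self, t):
        """Closed-form pooled dwell CDF  sum_i w_i (1 - exp(-k_d,i t))."""
        t = np.asarray(t, dtype=float)[..., None]
        return np.sum(self.weights * (1.0 - np.exp(-self.k_d * t)), axis=-1)

    def discrete_dwell_cdf(self, n_frames, frame_interval_s):
        """CDF of the frame-quantized measured dwell at ``n_frames`` frames.

        An event of true duration tau starting at a uniform phase u within a
        frame spans 1 + floor((u + tau)/dt) frames, so the measured dwell
        n*dt satisfies  P(span <= n) = (1/dt) * int_0^dt F(n dt - u) du.
        For an exponential mixture this integral is analytic:

            P = sum_i w_i [1 - exp(-k_i n dt) (exp(k_i dt) - 1) / (k_i dt)]
        """
        n = np.asarray(n_frames, dtype=float)[..., None]
        dt = float(frame_interval_s)
        kd = self.k_d
        return np.sum(
            self.weights
            * (1.0 - np.exp(-kd * n * dt) * (np.expm1(kd * dt)) / (kd * dt)),
            axis=-1,
        )


@dataclass
class SiteMap:
    """Realized adsorption sites: positions plus per-site kinetic parameters."""

    x_nm: np.ndarray
    y_nm: np.ndarray
    k_d: np.ndarray
    k_a: np.ndarray
    component: np.ndarray
    spec: ParticleSpec | None = None

    def __len__(self) -> int:
        return len(self.x_nm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": np.arange(len(self)),
                "x_nm": self.x_nm,
                "y_nm": self.y_nm,
                "k_d_per_s": self.k_d,
                "k_a_per_s": self.k_a,
                "component": self.component,
            }
        )


@dataclass(frozen=True)
class ImagingSpec:
    """Camera, optics and light-sheet parameters for one acquisition.

    Defaults follow a HILO light-sheet single-molecule setup: 32-ms frames,
    100-nm pixels, a 130-nm Gaussian PSF and a 2.3-um FWHM sheet.
    ``background`` is in expected photons per pixel per frame and absorbs the
    haze of freely diffusing analyte; ``read_noise`` is Gaussian, in
    electrons rms.
    """

    pixel_size_nm: float = 100.0
    frame_interval_s: float = 0.032
    n_frames: int = 2000
    shape: tuple[int, int] = (64, 64)  # (rows, cols)
    psf_sigma_nm: float = 130.0
    photons_per_frame: float = 800.0
    background: float = 10.0
    read_noise: float = 1.6
    sheet_fwhm_nm: float = 2300.0
    sheet_center_z_nm: float = 0.0

    def __post_init__(self):
        for name in (
            "pixel_size_nm",
            "frame_interval_s",
            "psf_sigma_nm",
            "photons_per_frame",
            "sheet_fwhm_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.background < 0 or self.read_noise < 0:
            raise ValueError("background and read_noise must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def fov_nm(self) -> tuple[float, float]:
        """(height, width) of the field of view in nm."""
        return (self.shape[0] * self.pixel_size_nm, self.shape[1] * self.pixel_size_nm)

    @property
    def sheet_weight(self) -> float:
        """Relative axial illumination of the imaged slice.

        Gaussian sheet profile in z; the slice sits ``sheet_center_z_nm``
        away from the sheet waist.
        """
        z = self.sheet_center_z_nm
        return float(np.exp(-4.0 * np.log(2.0) * (z / self.sheet_fwhm_nm) ** 2))


def sample_accessible(spec: ParticleSpec, n: int, rng: np.random.Generator):
    """Sample ``n`` points uniformly over the accessible elliptical annulus.

    In elliptical coordinates (x = a rho cos th, y = b rho sin th) the area
    element is a b rho drho dth, so uniformity requires rho^2 ~ U[(1-f)^2, 1].
    """
    f = spec.accessible_fraction
    rho = np.sqrt(rng.uniform((1.0 - f) ** 2, 1.0, size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    xp = spec.a_nm * rho * np.cos(theta)
    yp = spec.b_nm * rho * np.sin(theta)
    c, s = np.cos(spec.tilt_rad), np.sin(spec.tilt_rad)
    x = c * xp - s * yp + spec.center_xy[0]
    y = s * xp + c * yp + spec.center_xy[1]
    return x, y


def generate_site_map(
    spec: ParticleSpec, mix: KineticMixture, seed: int | np.random.Generator
) -> SiteMap:
    """Scatter adsorption sites over the accessible shell.

    The site count is Poisson(site_density x accessible area); positions are
    uniform over the annulus and kinetic classes are drawn i.i.d. from the
    mixture.
    """
    rng = np.random.default_rng(seed)
    area = spec.accessible_area_um2
    if area <= 0:
        raise ValueError("particle has zero accessible area")
    n = int(rng.poisson(spec.site_density_per_um2 * area))
    x, y = sample_accessible(spec, n, rng)
    comp = rng.choice(len(mix.components), size=n, p=mix.weights)
    return SiteMap(
        x_nm=x,
        y_nm=y,
        k_d=mix.k_d[comp],
        k_a=mix.k_a[comp],
        component=comp,
        spec=spec,
    )


def simulate_events(
    sites: SiteMap,
    duration_s: float,
    seed: int | np.random.Generator,
    bleach_rate_per_s: float = 0.0,
) -> pd.DataFrame:
    """Draw adsorption events for every site over one acquisition.

    Per site, arrivals follow a homogeneous Poisson process with rate k_a
    (non-blocking: overlapping events at one site are allowed, appropriate
    for low nanomolar occupancy) and each dwell is Exponential(1/k_d).
    ``bleach_rate_per_s`` > 0 truncates dwells by an independent exponential
    photobleaching clock (off by default).

    Returns an event table with columns
    event_id, site_id, x_nm, y_nm, t_start_s, dwell_s, sorted by start time.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(sites.k_a * duration_s)
    total = int(counts.sum())
    site_id = np.repeat(np.arange(len(sites)), counts)
    t_start = rng.uniform(0.0, duration_s, size=total)
    dwell = rng.exponential(1.0 / sites.k_d[site_id]) if total else np.empty(0)
    if bleach_rate_per_s > 0 and total:
        dwell = np.minimum(dwell, rng.exponential(1.0 / bleach_rate_per_s, size=total))
    df = pd.DataFrame(
        {
            "event_id": np.arange(total),
            "site_id": site_id,
            "x_nm": sites.x_nm[site_id],
            "y_nm": sites.y_nm[site_id],
            "t_start_s": t_start,
            "dwell_s": dwell,
        }
    )
    df = df.sort_values("t_start_s", ignore_index=True)
    df["event_id"] = np.arange(len(df))
    return df


def _frame_span(t_start, dwell, dt, n_frames):
    """First and last frame index each event touches (clipped to the movie)."""
    k0 = np.floor(t_start / dt).astype(int)
    k1 = np.floor((t_start + dwell) / dt).astype(int)
    return np.clip(k0, 0, n_frames - 1), np.clip(k1, 0, n_frames - 1)


def truth_localizations(events: pd.DataFrame, imaging: ImagingSpec) -> pd.DataFrame:
    """Ideal per-frame detections implied by the ground-truth events.

    One row per (event, frame) pair with the event's true position and the
    fractional temporal overlap with that frame.  Useful for testing the
    linking and dwell machinery in isolation from camera noise.
    """
    dt = imaging.frame_interval_s
    nf = imaging.n_frames
    rows = []
    for ev in events.itertuples(index=False):
        if ev.t_start_s >= nf * dt or ev.t_start_s + ev.dwell_s <= 0:
            continue
        k0, k1 = _frame_span(
            np.array([ev.t_start_s]), np.array([ev.dwell_s]), dt, nf
        )
        for k in range(int(k0[0]), int(k1[0]) + 1):
            frac = (min(ev.t_start_s + ev.dwell_s, (k + 1) * dt) - max(ev.t_start_s, k * dt)) / dt
            rows.append((k, ev.x_nm, ev.y_nm, frac, ev.event_id))
    df = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "overlap", "event_id"])
    return df.sort_values(["frame", "event_id"], ignore_index=True)


def render_movie(
    events: pd.DataFrame,
    imaging: ImagingSpec,
    seed: int | np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Render the camera movie for a set of adsorption events.

    Every event active during a frame adds a pixel-integrated symmetric
    Gaussian with expected photons = photons_per_frame x (fractional overlap
    of the event with the frame) x (axial sheet weight).  With ``noise``,
    pixel values are Poisson(signal + background) plus Gaussian read noise,
    rounded and returned as uint16; without, the expected photon image is
    returned as float64 (useful as a noiseless oracle).
    """
    ny, nx = imaging.shape
    dt = imaging.frame_interval_s
    p = imaging.pixel_size_nm
    half = int(np.ceil(4.5 * imaging.psf_sigma_nm / p))
    signal = np.zeros((imaging.n_frames, ny, nx), dtype=float)
    w_sheet = imaging.sheet_weight

    if len(events):
        k0, k1 = _frame_span(
            events["t_start_s"].to_numpy(),
            events["dwell_s"].to_numpy(),
            dt,
            imaging.n_frames,
        )
        xs = events["x_nm"].to_numpy()
        ys = events["y_nm"].to_numpy()
        t0 = events["t_start_s"].to_numpy()
        t1 = t0 + events["dwell_s"].to_numpy()
        for i in range(len(events)):
            cc = int(xs[i] / p)
            rc = int(ys[i] / p)
            rows = np.arange(max(rc - half, 0), min(rc + half + 1, ny))
            cols = np.arange(max(cc - half, 0), min(cc + half + 1, nx))
            if rows.size == 0 or cols.size == 0:
                continue
            patch = spot_patch(rows, cols, xs[i], ys[i], imaging.psf_sigma_nm, p)
            for k in range(k0[i], k1[i] + 1):
                frac = (min(t1[i], (k + 1) * dt) - max(t0[i], k * dt)) / dt
                if frac <= 0:
                    continue
                signal[k, rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1] += (
                    imaging.photons_per_frame * frac * w_sheet * patch
                )

    expected = signal + imaging.background
    if not noise:
        return expected
    rng = np.random.default_rng(seed)
    out = rng.poisson(expected).astype(float)
    if imaging.read_noise > 0:
        out += rng.normal(0.0, imaging.read_noise, size=out.shape)
    return np.clip(np.rint(out), 0, 65535).astype(np.uint16)
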