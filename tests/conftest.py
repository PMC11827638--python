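"""Shared fixtures: expensive end-to-end simulations are session-scoped so
the recovery suites and acceptance tests reuse one set of rendered movies.
"""

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import settings

import smchrom as sc
from smchrom.config import RunConfig
from smchrom.kinetics import dwell_distribution, link_events
from smchrom.pipeline import run_pipeline

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def recovery_results(tmp_path_factory):
    """Full simulate->localize->access runs for shell fractions 0.37/0.64/1.

    Study conditions: default imaging (32-ms frames, 800 photons/frame,
    130-nm PSF), default site density and kinetic mixture, four pooled
    2000-frame acquisitions per particle.  The 0.37 case uses the 1.35-um
    superficially-porous geometry; the others a 2.5-um-radius particle.
    """
    out = {}
    for f, ab in [(0.37, 1350.0), (0.64, 2500.0), (1.0, 2500.0)]:
        cfg = RunConfig(seed=1)
        cfg.particle.accessible_fraction = f
        cfg.particle.a_nm = cfg.particle.b_nm = ab
        cfg.stages = ["simulate", "localize", "access"]
        outdir = tmp_path_factory.mktemp(f"recovery_f{int(100 * f):03d}")
        products = run_pipeline(cfg, outdir=outdir)
        out[f] = products
    return out


@pytest.fixture(scope="session")
def single_exponential_movie_dwells():
    """Rendered-movie dwell sample for one-component first-order kinetics.

    k_d = 4/s (mean dwell 0.25 s ~ 7.8 frames), sparse arrivals so spots
    rarely overlap; two pooled 2000-frame acquisitions at default SNR.
    Returns (dwells, true sample mean dwell, k_d).
    """
    spec = sc.ParticleSpec(a_nm=2500.0, b_nm=2500.0, site_density_per_um2=40.0)
    mix = sc.KineticMixture(((1.0, 4.0, 0.008),))
    sites = sc.generate_site_map(spec, mix, 5)
    im = sc.ImagingSpec(n_frames=2000)
    dwells = []
    true_dwells = []
    for a in range(2):
        events = sc.simulate_events(sites, im.duration_s, 6 + a)
        true_dwells.append(events["dwell_s"].to_numpy())
        movie = sc.render_movie(events, im, 8 + a)
        locs = sc.localize_movie(movie)
        linked = link_events(locs, n_frames=im.n_frames)
        dwells.append(dwell_distribution(linked).dwells_s)
    return (
        np.concatenate(dwells),
        float(np.concatenate(true_dwells).mean()),
        4.0,
    )


@pytest.fixture(scope="session")
def mixture_truth_dwells():
    """Ideal-detection dwell sample from a two-component kinetic mixture.

    Events are converted to per-frame truth localizations (no camera) and
    linked, isolating the event-construction machinery; n >= 5000.
    Returns (dwells, mixture, frame_interval).
    """
    mix = sc.KineticMixture(((0.5, 10.0, 0.0133), (0.5, 0.5, 0.0133)))
    spec = sc.ParticleSpec(a_nm=2500.0, b_nm=2500.0, site_density_per_um2=60.0)
    sites = sc.generate_site_map(spec, mix, 8)
    im = sc.ImagingSpec(n_frames=12000)
    events = sc.simulate_events(sites, im.duration_s, 9)
    truth = sc.truth_localizations(events, im)
    linked = link_events(truth, n_frames=im.n_frames)
    dwells = dwell_distribution(linked).dwells_s
    return dwells, mix, im.frame_interval_s
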