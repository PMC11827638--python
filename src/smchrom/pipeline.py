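"""Reproducible end-to-end runs: simulate -> localize -> access -> kinetics
-> elute, any contiguous sub-chain.

Every run writes its artifacts plus a manifest (config hash, seed,
library versions) into the output directory, so a figure-style output can
be re-created from the manifest alone.  All randomness flows from the
single config seed through named substreams.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accessibility import assess_accessibility
from .config import RunConfig
from .elution import model_elution
from .errors import PipelineError
from .io import (
    load_movie,
    read_events,
    read_localizations,
    save_movie,
    write_events,
    write_json,
    write_localizations,
    write_profile,
    write_sites,
    write_truth_events,
)
from .kinetics import (
    cluster_sites,
    desorption_rate,
    dwell_distribution,
    link_events,
    site_energetics,
)
from .localize import LocalizeParams, localize_movie
from .synthetic import (
    ImagingSpec,
    KineticMixture,
    ParticleSpec,
    generate_site_map,
    render_movie,
    simulate_events,
)

__all__ = ["run_pipeline", "stage_seed", "build_imaging", "build_particle",
           "build_mixture", "build_localize_params"]

log = logging.getLogger("smchrom")

# Fixed per-stage offsets keep substreams independent of which stages run;
# repeated acquisitions of one particle advance within a stage's stream.
_STAGE_OFFSETS = {"sites": 11, "events": 23, "render": 37}


def stage_seed(seed: int, stage: str, acquisition: int = 0) -> int:
    """Derive a reproducible per-stage seed below 2**31 from the run seed."""
    return (
        int(seed) * 1000003 + _STAGE_OFFSETS[stage] + 101 * int(acquisition)
    ) % (2**31 - 1)


def build_particle(cfg: RunConfig) -> ParticleSpec:
    p = cfg.particle
    return ParticleSpec(
        center_xy=(p.center_x_nm, p.center_y_nm),
        a_nm=p.a_nm,
        b_nm=p.b_nm,
        tilt_rad=p.tilt_rad,
        accessible_fraction=p.accessible_fraction,
        site_density_per_um2=p.site_density_per_um2,
    )


def build_mixture(cfg: RunConfig) -> KineticMixture:
    return KineticMixture(tuple(tuple(c) for c in cfg.mixture.components))


def build_imaging(cfg: RunConfig) -> ImagingSpec:
    im = cfg.imaging
    return ImagingSpec(
        pixel_size_nm=im.pixel_size_nm,
        frame_interval_s=im.frame_interval_s,
        n_frames=im.n_frames,
        shape=tuple(im.shape),
        psf_sigma_nm=im.psf_sigma_nm,
        photons_per_frame=im.photons_per_frame,
        background=im.background,
        read_noise=im.read_noise,
        sheet_fwhm_nm=im.sheet_fwhm_nm,
        sheet_center_z_nm=im.sheet_center_z_nm,
    )


def build_localize_params(cfg: RunConfig) -> LocalizeParams:
    lc = cfg.localize
    return LocalizeParams(
        pixel_size_nm=cfg.imaging.pixel_size_nm,
        psf_sigma_nm=cfg.imaging.psf_sigma_nm,
        threshold_k=lc.threshold_k,
        min_separation_px=lc.min_separation_px,
        roi_half=lc.roi_half,
        n_min_photons=lc.n_min_photons,
        sigma_window=tuple(lc.sigma_window),
    )


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the configured stage chain and write all artifacts.

    Returns a dict of in-memory products keyed by stage.  Raises
    ``PipelineError`` naming the missing input when a stage is started
    without its upstream product (on disk or in memory).
    """
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    imaging = build_imaging(config)
    products: dict = {}

    if "simulate" in config.stages:
        _stage_simulate(config, imaging, out, products)
    if "localize" in config.stages:
        _stage_localize(config, imaging, out, products)
    if "access" in config.stages:
        _stage_access(config, out, products)
    if "kinetics" in config.stages:
        _stage_kinetics(config, imaging, out, products)
    if "elute" in config.stages:
        _stage_elute(config, imaging, out, products)

    manifest = {
        "smchrom_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "versions": _library_versions(),
    }
    config.to_yaml(out / "config.yaml")
    write_json(manifest, out / "manifest.json")
    products["manifest"] = manifest
    return products


def _library_versions() -> dict:
    import scipy
    import skimage

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
    }


def _stage_simulate(config, imaging, out, products):
    log.info("simulate: placing sites and drawing events")
    particle = build_particle(config)
    mixture = build_mixture(config)
    sites = generate_site_map(particle, mixture, stage_seed(config.seed, "sites"))
    n_acq = config.imaging.n_acquisitions
    all_events = []
    movies = []
    for a in range(n_acq):
        events = simulate_events(
            sites,
            imaging.duration_s,
            stage_seed(config.seed, "events", a),
            bleach_rate_per_s=config.elution.bleach_rate_per_s,
        )
        events["acquisition"] = a
        movie = render_movie(events, imaging, stage_seed(config.seed, "render", a))
        save_movie(out / f"movie_{a:02d}.tif", movie, imaging)
        all_events.append(events)
        movies.append(movie)
    events = pd.concat(all_events, ignore_index=True)
    sites.to_frame().to_csv(out / "truth_sites.csv", index=False)
    write_truth_events(events, out / "truth_events.csv")
    log.info("simulate: %d sites, %d events over %d acquisition(s)",
             len(sites), len(events), n_acq)
    products["simulate"] = {"sites": sites, "events": events, "movies": movies}


def _stage_localize(config, imaging, out, products):
    if "simulate" in products:
        movies = products["simulate"]["movies"]
    else:
        paths = sorted(out.glob("movie_*.tif"))
        if not paths:
            raise PipelineError(
                "localize needs movies: run the simulate stage or place "
                f"movie_*.tif in {out}"
            )
        movies = [load_movie(p)[0] for p in paths]
    params = build_localize_params(config)
    pooled = []
    rejections: dict = {}
    for a, movie in enumerate(movies):
        log.info("localize: acquisition %d, %d frames", a, movie.shape[0])
        locs = localize_movie(movie, params)
        locs["acquisition"] = a
        for key, val in locs.attrs.get("rejections", {}).items():
            rejections[key] = rejections.get(key, 0) + val
        pooled.append(locs)
    locs = pd.concat(pooled, ignore_index=True)
    locs.attrs["rejections"] = rejections
    write_localizations(locs, out / "localizations.csv")
    log.info("localize: %d localizations (rejections: %s)", len(locs), rejections)
    products["localize"] = {"localizations": locs}


def _require_localizations(out, products, stage):
    if "localize" in products:
        return products["localize"]["localizations"]
    path = out / "localizations.csv"
    if path.exists():
        return read_localizations(path)
    raise PipelineError(
        f"{stage} needs a localization table: run the localize stage or place "
        f"localizations.csv in {out}"
    )


def _stage_access(config, out, products):
    locs = _require_localizations(out, products, "access")
    ac = config.access
    result = assess_accessibility(
        locs,
        map_pixel_nm=ac.map_pixel_nm,
        closing_radius_px=ac.closing_radius_px,
        min_localizations=ac.min_localizations,
        outlier_tol=ac.outlier_tol,
    )
    write_json(result.to_dict(), out / "accessibility.json")
    pd.DataFrame(
        {
            "percent_r": result.cdf_grid_percent_r,
            "cumulative_fraction": result.cdf,
        }
    ).to_csv(out / "depth_cdf.csv", index=False)
    log.info("access: d99 = %.1f %%r, Ap/Ai = %.3f",
             result.d99_percent_r, result.ratio)
    products["access"] = {"result": result}


def _stage_kinetics(config, imaging, out, products):
    locs = _require_localizations(out, products, "kinetics")
    kc = config.kinetics
    # Acquisitions are linked independently: frame numbering restarts and
    # censoring applies at each movie's own boundaries.
    if "acquisition" not in locs.columns:
        locs = locs.assign(acquisition=0)
    linked = []
    for a, group in locs.groupby("acquisition", sort=True):
        ev = link_events(
            group,
            r_link_nm=kc.r_link_nm,
            max_gap=kc.max_gap,
            frame_interval_s=imaging.frame_interval_s,
            n_frames=imaging.n_frames,
        )
        ev["acquisition"] = a
        linked.append(ev)
    events = pd.concat(linked, ignore_index=True)
    n_acquisitions = locs["acquisition"].nunique()
    write_events(events, out / "events.csv")
    dwells = dwell_distribution(events, frame_interval_s=imaging.frame_interval_s)
    sites, labels = cluster_sites(
        events,
        site_radius_nm=kc.site_radius_nm,
        duration_s=imaging.duration_s * n_acquisitions,
    )
    sites = site_energetics(
        sites,
        concentration_M=kc.concentration_nM * 1e-9,
        temperature_K=kc.temperature_K,
    )
    write_sites(sites, out / "sites.csv")
    summary = {
        "n_events": int(len(events)),
        "n_uncensored": int(dwells.n),
        "n_censored": int(dwells.n_censored),
        "mean_dwell_s": dwells.mean_s,
        "kd_global_per_s": desorption_rate(dwells.dwells_s, imaging.frame_interval_s),
        "n_sites": int(len(sites)),
    }
    write_json(summary, out / "kinetics.json")
    log.info("kinetics: %d events at %d sites, mean dwell %.3f s",
             len(events), len(sites), dwells.mean_s)
    products["kinetics"] = {
        "events": events,
        "dwells": dwells,
        "sites": sites,
        "labels": labels,
        "summary": summary,
    }


def _stage_elute(config, imaging, out, products):
    if "kinetics" in products:
        dwells = products["kinetics"]["dwells"]
        dwell_values = dwells.dwells_s
    elif (out / "events.csv").exists():
        events = read_events(out / "events.csv")
        dwell_values = dwell_distribution(
            events, frame_interval_s=imaging.frame_interval_s
        ).dwells_s
    else:
        raise PipelineError(
            "elute needs dwell times: run the kinetics stage or place "
            f"events.csv in {out}"
        )
    ec = config.elution
    profile = model_elution(
        dwell_values,
        n_bar=ec.n_bar,
        t_m_s=ec.t_m_s,
        min_dt_s=imaging.frame_interval_s / 4.0,
    )
    write_profile(profile, out / "elution_profile.csv")
    moments = profile.moments()
    write_json(moments.to_dict(), out / "elution_moments.json")
    log.info("elute: centroid %.2f s, skew %.2f", moments.center_s, moments.skew)
    products["elute"] = {"profile": profile, "moments": moments}
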