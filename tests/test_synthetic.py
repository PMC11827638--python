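"""Simulator: site placement geometry, event statistics, camera rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import smchrom as sc
from smchrom.synthetic import sample_accessible


def make_sites(k_d, k_a, n=1, x=3200.0, y=3200.0):
    return sc.SiteMap(
        x_nm=np.full(n, x),
        y_nm=np.full(n, y),
        k_d=np.full(n, k_d),
        k_a=np.full(n, k_a),
        component=np.zeros(n, dtype=int),
    )


class TestSiteMap:
    def test_sites_confined_to_accessible_annulus(self, rng):
        """Site radii obey rho in [1-f, 1] exactly, even for a tilted
        eccentric outline."""
        spec = sc.ParticleSpec(
            a_nm=2800.0, b_nm=2100.0, tilt_rad=0.6, accessible_fraction=0.37
        )
        sites = sc.generate_site_map(spec, sc.KineticMixture.default(), rng)
        rho = spec.rho(sites.x_nm, sites.y_nm)
        assert len(sites) > 100
        assert rho.min() >= 1.0 - spec.accessible_fraction - 1e-12
        assert rho.max() <= 1.0 + 1e-12

    def test_superficially_porous_shell_depth(self, rng):
        """A 0.5-um shell on a 1.35-um radius keeps every site within
        500 nm of the particle edge."""
        f = 0.5 / 1.35
        spec = sc.ParticleSpec(a_nm=1350.0, b_nm=1350.0, accessible_fraction=f)
        sites = sc.generate_site_map(spec, sc.KineticMixture.default(), rng)
        dist_from_edge = (1.0 - spec.rho(sites.x_nm, sites.y_nm)) * 1350.0
        assert dist_from_edge.max() <= 500.0 + 1e-9

    def test_full_disc_reaches_center(self, rng):
        """With f = 1 a dense site map approaches the particle center."""
        spec = sc.ParticleSpec(accessible_fraction=1.0, site_density_per_um2=500.0)
        sites = sc.generate_site_map(spec, sc.KineticMixture.default(), rng)
        assert spec.rho(sites.x_nm, sites.y_nm).min() < 0.05

    def test_site_count_poisson_mean(self):
        """Density 10/um^2 over a 20-um^2 accessible disc averages 200
        sites (within 3 SE over 500 seeds)."""
        radius = np.sqrt(20.0 / np.pi) * 1e3
        spec = sc.ParticleSpec(
            a_nm=radius, b_nm=radius, site_density_per_um2=10.0
        )
        mix = sc.KineticMixture.default()
        counts = [len(sc.generate_site_map(spec, mix, s)) for s in range(500)]
        se = np.sqrt(200.0 / 500.0)
        assert abs(np.mean(counts) - 200.0) < 3.0 * se

    def test_mixture_components_drawn_iid(self, rng):
        mix = sc.KineticMixture(((0.7, 10.0, 0.01), (0.3, 1.0, 0.01)))
        spec = sc.ParticleSpec(site_density_per_um2=100.0)
        sites = sc.generate_site_map(spec, mix, rng)
        frac = np.mean(sites.component == 0)
        assert abs(frac - 0.7) < 3.0 * np.sqrt(0.21 / len(sites))
        assert set(np.unique(sites.k_d)) == {10.0, 1.0}


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"a_nm": 100.0, "b_nm": 200.0},  # a < b
            {"accessible_fraction": 0.0},
            {"accessible_fraction": 1.2},
            {"site_density_per_um2": -1.0},
        ],
    )
    def test_bad_particle_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sc.ParticleSpec(**kwargs)

    @pytest.mark.parametrize(
        "components",
        [
            (),
            ((0.5, 1.0, 0.1),),  # weights don't sum to 1
            ((1.0, -2.0, 0.1),),  # k_d <= 0
            ((1.0, 1.0, -0.1),),  # k_a < 0
        ],
    )
    def test_bad_mixture_rejected(self, components):
        with pytest.raises(ValueError):
            sc.KineticMixture(components)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            sc.simulate_events(make_sites(1.0, 1.0), 0.0, 1)


class TestEvents:
    def test_zero_arrival_rate_gives_empty_table(self):
        events = sc.simulate_events(make_sites(k_d=1.0, k_a=0.0, n=50), 100.0, 3)
        assert len(events) == 0
        assert list(events.columns) == sc.synthetic.EVENT_COLUMNS

    def test_exponential_dwell_mean(self):
        """~1e4 dwells at k_d = 2/s average 0.5 s within 3 SE."""
        events = sc.simulate_events(make_sites(k_d=2.0, k_a=160.0), 62.5, 4)
        dwell = events["dwell_s"].to_numpy()
        assert len(dwell) > 5000
        se = dwell.std(ddof=1) / np.sqrt(len(dwell))
        assert abs(dwell.mean() - 0.5) < 3.0 * se

    def test_mixture_dwell_cdf(self):
        """Pooled dwells from a 2-component mixture follow the closed-form
        mixture CDF (KS < 0.02 at n ~ 1e4)."""
        mix = sc.KineticMixture(((0.5, 10.0, 80.0), (0.5, 0.5, 80.0)))
        sites = sc.SiteMap(
            x_nm=np.zeros(2),
            y_nm=np.zeros(2),
            k_d=mix.k_d.copy(),
            k_a=mix.k_a.copy(),
            component=np.arange(2),
        )
        events = sc.simulate_events(sites, 65.0, 5)
        dwell = events["dwell_s"].to_numpy()
        assert len(dwell) > 8000
        res = stats.kstest(dwell, lambda t: mix.dwell_cdf(t))
        assert res.statistic < 0.02

    def test_pooled_dwell_mean_matches_mixture_expectation(self, rng):
        """Default-mixture simulation mean dwell lands within 3 SE of
        sum_i w_i / k_d,i."""
        mix = sc.KineticMixture.default()
        sites = sc.generate_site_map(
            sc.ParticleSpec(site_density_per_um2=400.0), mix, rng
        )
        sites.k_a[:] = 0.05
        events = sc.simulate_events(sites, 64.0, 6)
        dwell = events["dwell_s"].to_numpy()
        se = dwell.std(ddof=1) / np.sqrt(len(dwell))
        assert abs(dwell.mean() - mix.mean_dwell_s) < 3.0 * se

    def test_bleaching_truncates_dwells(self):
        sites = make_sites(k_d=1.0, k_a=20.0)
        long_lived = sc.simulate_events(sites, 200.0, 7)
        bleached = sc.simulate_events(sites, 200.0, 7, bleach_rate_per_s=10.0)
        assert bleached["dwell_s"].mean() < 0.5 * long_lived["dwell_s"].mean()

    @given(st.integers(min_value=0, max_value=10_000))
    def test_dwells_positive_and_positions_at_sites(self, seed):
        sites = make_sites(k_d=5.0, k_a=2.0, n=3, x=1000.0, y=2000.0)
        events = sc.simulate_events(sites, 10.0, seed)
        assert (events["dwell_s"] > 0).all()
        assert (events["t_start_s"] >= 0).all()
        assert set(events["x_nm"]).issubset({1000.0})


class TestRender:
    def test_rendering_bit_exact_for_fixed_seed(self):
        sites = make_sites(k_d=5.0, k_a=1.0)
        events = sc.simulate_events(sites, 3.2, 8)
        im = sc.ImagingSpec(n_frames=100, shape=(32, 32))
        a = sc.render_movie(events, im, 42)
        b = sc.render_movie(events, im, 42)
        c = sc.render_movie(events, im, 43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_empty_movie_is_background(self):
        im = sc.ImagingSpec(n_frames=50, shape=(32, 32))
        movie = sc.render_movie(pd.DataFrame(columns=sc.synthetic.EVENT_COLUMNS), im, 9)
        n_pix = movie.size
        sd = np.sqrt(im.background + im.read_noise**2)
        assert abs(movie.mean() - im.background) < 3.0 * sd / np.sqrt(n_pix)

    def test_noiseless_centroid_matches_truth(self):
        """The photon-weighted centroid of a noiseless long-event render
        reproduces the emitter position to better than 1 nm."""
        im = sc.ImagingSpec(n_frames=1, shape=(21, 21), photons_per_frame=5000.0)
        x0, y0 = 1043.0, 1061.0
        events = pd.DataFrame(
            {
                "event_id": [0],
                "site_id": [0],
                "x_nm": [x0],
                "y_nm": [y0],
                "t_start_s": [0.0],
                "dwell_s": [1.0],
            }
        )
        frame = sc.render_movie(events, im, noise=False)[0] - im.background
        cols = (np.arange(21) + 0.5) * im.pixel_size_nm
        cx = (frame.sum(axis=0) * cols).sum() / frame.sum()
        cy = (frame.sum(axis=1) * cols).sum() / frame.sum()
        assert abs(cx - x0) < 1.0
        assert abs(cy - y0) < 1.0

    def test_photon_linearity(self):
        events = pd.DataFrame(
            {
                "event_id": [0],
                "site_id": [0],
                "x_nm": [1600.0],
                "y_nm": [1600.0],
                "t_start_s": [0.0],
                "dwell_s": [1.0],
            }
        )
        im1 = sc.ImagingSpec(n_frames=1, shape=(32, 32), photons_per_frame=500.0)
        im2 = sc.ImagingSpec(n_frames=1, shape=(32, 32), photons_per_frame=1000.0)
        s1 = sc.render_movie(events, im1, noise=False) - im1.background
        s2 = sc.render_movie(events, im2, noise=False) - im2.background
        assert np.allclose(s2, 2.0 * s1)

    def test_axial_sheet_attenuates_signal(self):
        """A slice half a sheet-FWHM from the waist receives half the
        photons (Gaussian axial envelope)."""
        centered = sc.ImagingSpec(n_frames=1)
        offset = sc.ImagingSpec(n_frames=1, sheet_center_z_nm=1150.0)
        assert centered.sheet_weight == pytest.approx(1.0)
        assert offset.sheet_weight == pytest.approx(0.5, rel=1e-6)

    def test_truth_localizations_span_and_overlap(self):
        """An event spanning frame boundaries yields one truth localization
        per touched frame with the correct fractional overlap."""
        im = sc.ImagingSpec(n_frames=100)
        events = pd.DataFrame(
            {
                "event_id": [0],
                "site_id": [0],
                "x_nm": [500.0],
                "y_nm": [500.0],
                "t_start_s": [10 * 0.032 + 0.016],
                "dwell_s": [0.032],
            }
        )
        truth = sc.truth_localizations(events, im)
        assert list(truth["frame"]) == [10, 11]
        assert truth["overlap"].to_numpy() == pytest.approx([0.5, 0.5])


def test_sample_accessible_uniform_depth_distribution(rng):
    """Area-uniform sampling of the annulus: rho^2 is uniform on
    [(1-f)^2, 1]."""
    spec = sc.ParticleSpec(a_nm=2000.0, b_nm=1500.0, accessible_fraction=0.5)
    x, y = sample_accessible(spec, 20_000, rng)
    rho2 = spec.rho(x, y) ** 2
    lo = (1.0 - 0.5) ** 2
    res = stats.kstest(rho2, stats.uniform(loc=lo, scale=1.0 - lo).cdf)
    assert res.statistic < 0.02
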