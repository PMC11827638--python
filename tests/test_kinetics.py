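"""Event linking, dwell-time distributions, site clustering, energetics."""

import numpy as np
import pandas as pd
import pytest

import smchrom as sc
from smchrom.errors import DataError
from smchrom.kinetics import (
    cluster_sites,
    desorption_rate,
    dwell_distribution,
    equilibrium_free_energy,
    link_events,
    site_energetics,
)

DT = 0.032


def loc_table(rows):
    return pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"])


class TestLinking:
    def test_isolated_localization_is_single_frame_event(self):
        events = link_events(loc_table([(5, 100.0, 100.0)]), n_frames=100)
        assert len(events) == 1
        ev = events.iloc[0]
        assert ev.n_frames == 1
        assert ev.dwell_s == pytest.approx(DT)
        assert not ev.censored_start and not ev.censored_end

    def test_consecutive_frames_linked(self):
        events = link_events(
            loc_table([(5, 100.0, 100.0), (6, 130.0, 90.0), (7, 110.0, 105.0)]),
            n_frames=100,
        )
        assert len(events) == 1
        assert events.iloc[0].n_frames == 3
        assert events.iloc[0].n_localizations == 3

    def test_single_frame_blink_bridged(self):
        """A one-frame gap (blink) is tolerated; the span counts the gap."""
        events = link_events(
            loc_table([(5, 100.0, 100.0), (7, 110.0, 100.0)]), n_frames=100
        )
        assert len(events) == 1
        assert events.iloc[0].n_frames == 3
        assert events.iloc[0].n_localizations == 2

    def test_two_frame_gap_splits(self):
        events = link_events(
            loc_table([(5, 100.0, 100.0), (8, 100.0, 100.0)]), n_frames=100
        )
        assert len(events) == 2

    def test_simultaneous_distant_events_never_merged(self):
        rows = [(f, 500.0, 500.0) for f in range(5, 10)]
        rows += [(f, 1500.0, 500.0) for f in range(5, 10)]
        events = link_events(loc_table(rows), n_frames=100)
        assert len(events) == 2
        assert sorted(events.n_frames) == [5, 5]

    def test_boundary_events_flagged_censored(self):
        events = link_events(
            loc_table([(0, 100.0, 100.0), (99, 900.0, 900.0)]), n_frames=100
        )
        assert events.censored_start.tolist() == [True, False]
        assert events.censored_end.tolist() == [False, True]

    def test_event_count_and_localization_conservation(self, rng):
        """Events never outnumber localizations and linked localizations
        plus gap fills account for every frame span."""
        spec = sc.ParticleSpec(site_density_per_um2=50.0)
        sites = sc.generate_site_map(spec, sc.KineticMixture.default(), rng)
        im = sc.ImagingSpec(n_frames=500)
        events_true = sc.simulate_events(sites, im.duration_s, 31)
        truth = sc.truth_localizations(events_true, im)
        linked = link_events(truth, n_frames=im.n_frames)
        assert len(linked) <= len(truth)
        assert linked.n_localizations.sum() == len(truth)
        assert (linked.n_frames >= linked.n_localizations).all()
        assert (linked.dwell_s >= DT - 1e-12).all()


class TestDwellDistribution:
    def test_single_dwell_step_cdf(self):
        events = link_events(loc_table([(5, 0.0, 0.0)]), n_frames=100)
        dw = dwell_distribution(events)
        x, f = dw.ecdf()
        assert x.tolist() == [pytest.approx(DT)]
        assert f.tolist() == [1.0]

    def test_all_censored_rejected(self):
        events = link_events(loc_table([(0, 0.0, 0.0)]), n_frames=100)
        with pytest.raises(DataError):
            dwell_distribution(events)

    def test_censored_events_excluded_but_counted(self):
        events = link_events(
            loc_table([(0, 0.0, 0.0), (50, 900.0, 900.0)]), n_frames=100
        )
        dw = dwell_distribution(events)
        assert dw.n == 1
        assert dw.n_censored == 1

    def test_mixture_cdf_matches_discretized_closed_form(self, mixture_truth_dwells):
        """Linked-event dwell CDF agrees with the frame-quantized mixture
        law (KS < 0.03 at n >= 5000)."""
        dwells, mix, dt = mixture_truth_dwells
        assert len(dwells) >= 5000
        kmax = int(np.max(dwells) / dt) + 1
        k = np.arange(1, kmax + 1)
        model = mix.discrete_dwell_cdf(k, dt)
        empirical = np.searchsorted(np.sort(dwells), k * dt + 1e-9) / len(dwells)
        assert np.max(np.abs(empirical - model)) < 0.03
        assert empirical[-1] == pytest.approx(1.0)

    def test_no_dwell_below_frame_interval(self, mixture_truth_dwells):
        dwells, _, dt = mixture_truth_dwells
        assert dwells.min() >= dt - 1e-12


class TestRates:
    def test_movie_level_mean_dwell_within_ten_percent(
        self, single_exponential_movie_dwells
    ):
        """Uncensored linked-event mean dwell from rendered movies tracks
        the true mean dwell within 10% at default SNR."""
        dwells, true_mean, _ = single_exponential_movie_dwells
        assert abs(dwells.mean() - true_mean) / true_mean < 0.10

    def test_truth_level_corrected_rate_at_three_frame_dwells(self, rng):
        """With ideal detection the discretization-corrected estimator
        recovers k_d within 10% even at mean dwell = 3 frames."""
        kd = 1.0 / (3 * DT)
        spec = sc.ParticleSpec(site_density_per_um2=40.0)
        sites = sc.generate_site_map(spec, sc.KineticMixture(((1.0, kd, 0.02),)), rng)
        im = sc.ImagingSpec(n_frames=2000)
        events = sc.simulate_events(sites, im.duration_s, 33)
        truth = sc.truth_localizations(events, im)
        linked = link_events(truth, n_frames=im.n_frames)
        dw = dwell_distribution(linked)
        kd_hat = desorption_rate(dw.dwells_s, DT)
        assert abs(kd_hat - kd) / kd < 0.10

    def test_empty_dwell_sample_rejected(self):
        with pytest.raises(DataError):
            desorption_rate([], DT)


class TestSites:
    def make_events(self, positions, dwells):
        rows = []
        for (x, y), dwell in zip(positions, dwells):
            rows.append(
                {
                    "start_frame": 10,
                    "n_frames": int(round(dwell / DT)),
                    "n_localizations": int(round(dwell / DT)),
                    "dwell_s": dwell,
                    "x_nm": x,
                    "y_nm": y,
                    "censored_start": False,
                    "censored_end": False,
                }
            )
        return pd.DataFrame(rows)

    def test_coincident_events_form_one_site(self):
        events = self.make_events([(100.0, 100.0)] * 10, [0.1] * 10)
        sites, labels = cluster_sites(events, duration_s=64.0)
        assert len(sites) == 1
        assert sites.iloc[0].n_events == 10
        assert set(labels) == {0}

    def test_site_desorption_rate_is_inverse_mean_dwell(self):
        """The headline convention: a site with 0.5-s dwells has
        k_d = 1/t_D = 2/s."""
        events = self.make_events([(0.0, 0.0)] * 4, [0.5] * 4)
        sites, _ = cluster_sites(events, duration_s=100.0)
        assert sites.iloc[0].kd_per_s == pytest.approx(2.0)
        assert sites.iloc[0].ka_per_s == pytest.approx(0.04)

    def test_distant_clusters_are_separate_sites(self):
        events = self.make_events([(0.0, 0.0)] * 3 + [(1000.0, 0.0)] * 3, [0.1] * 6)
        sites, _ = cluster_sites(events, duration_s=64.0)
        assert len(sites) == 2

    def test_chained_events_single_linkage(self):
        """Single linkage: positions chained by sub-threshold steps share
        one site even when the extremes are far apart."""
        events = self.make_events([(0.0, 0.0), (50.0, 0.0), (100.0, 0.0)], [0.1] * 3)
        sites, _ = cluster_sites(events, site_radius_nm=60.0, duration_s=64.0)
        assert len(sites) == 1

    def test_missing_duration_rejected(self):
        events = self.make_events([(0.0, 0.0)], [0.1])
        with pytest.raises(DataError):
            cluster_sites(events)


class TestEnergetics:
    def test_unit_equilibrium_constant_zero_energy(self):
        assert equilibrium_free_energy(1.0) == 0.0

    def test_keq_ten_at_298K(self):
        """K_eq = 10 at 298 K gives dG = -RT ln 10 = -5.71 kJ/mol."""
        assert equilibrium_free_energy(10.0, 298.0) == pytest.approx(-5.71, abs=0.01)

    def test_site_table_energies(self):
        sites = pd.DataFrame(
            {
                "x_nm": [0.0],
                "y_nm": [0.0],
                "n_events": [10],
                "kd_per_s": [2.0],
                "ka_per_s": [0.01],
                "dG_kJ_mol": [np.nan],
            }
        )
        out = site_energetics(sites, concentration_M=1e-9, temperature_K=298.15)
        keq = 0.01 / (2.0 * 1e-9)
        expected = -8.314462618e-3 * 298.15 * np.log(keq)
        assert out.iloc[0].dG_kJ_mol == pytest.approx(expected)

    def test_heterogeneous_particle_energy_span(self, rng):
        """A mixed-kinetics particle yields per-site adsorption free
        energies spanning several kJ/mol."""
        spec = sc.ParticleSpec(site_density_per_um2=20.0)
        sites_map = sc.generate_site_map(spec, sc.KineticMixture.default(), rng)
        im = sc.ImagingSpec(n_frames=4000)
        events = sc.simulate_events(sites_map, im.duration_s, 35)
        truth = sc.truth_localizations(events, im)
        linked = link_events(truth, n_frames=im.n_frames)
        sites, _ = cluster_sites(linked, duration_s=im.duration_s)
        sites = site_energetics(sites, concentration_M=1e-9)
        dg = sites.dG_kJ_mol.dropna()
        multi = sites.n_events >= 3
        dg_multi = sites.dG_kJ_mol[multi].dropna()
        assert len(dg) > 50
        assert dg_multi.max() - dg_multi.min() > 2.0
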