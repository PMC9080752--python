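"""Stereology, density maps, mosaic geometry and spatial resolving power."""

import math

import numpy as np
import pytest

from ovk import synthetic as syn
from ovk.retinal_topography import (
    CountingSite,
    cone_mosaic_counts,
    density_map,
    lens_radius_for_srp,
    peak_density,
    scheaffer_ce,
    site_density,
    spatial_resolving_power,
    total_population,
)
from ovk.synthetic import elliptical_outline


def flat_sites(density, n_side=12, step=0.5, frame=0.0025, cls="ganglion", seed=0):
    """Deterministic uniform-density site grid (no sampling noise)."""
    count = int(round(density * frame))
    return [
        CountingSite(x * step, y * step, {cls: count}, frame, step)
        for x in range(-n_side // 2, n_side // 2 + 1)
        for y in range(-n_side // 2, n_side // 2 + 1)
    ]


class TestSiteDensity:
    def test_count_over_frame_area(self):
        s = CountingSite(0, 0, {"ganglion": 10}, 0.001, 0.5)
        assert site_density(s, "ganglion") == 10_000

    def test_zero_count_zero_density(self):
        s = CountingSite(0, 0, {"ganglion": 0}, 0.001, 0.5)
        assert site_density(s, "ganglion") == 0.0

    def test_doubling_frame_area_halves_density(self):
        a = CountingSite(0, 0, {"ganglion": 8}, 0.001, 0.5)
        b = CountingSite(0, 0, {"ganglion": 8}, 0.002, 0.5)
        assert site_density(a, "ganglion") == 2 * site_density(b, "ganglion")

    def test_frame_larger_than_grid_cell_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            CountingSite(0, 0, {"ganglion": 1}, 0.3, 0.5)


class TestTotalPopulation:
    def test_fractionator_formula_single_site(self):
        # asf = frame/grid² = 1/100; one site of 5 cells -> 500
        s = CountingSite(0, 0, {"ganglion": 5}, 0.0025, 0.5)
        assert total_population([s], "ganglion") == 500

    def test_all_zero_counts(self):
        sites = flat_sites(0.0)
        assert total_population(sites, "ganglion") == 0.0

    def test_mixed_grid_steps_error(self):
        a = CountingSite(0, 0, {"ganglion": 1}, 0.0025, 0.5)
        b = CountingSite(1, 0, {"ganglion": 1}, 0.0025, 0.25)
        with pytest.raises(ValueError, match="mixed grid steps"):
            total_population([a, b], "ganglion")

    def test_fractionator_unbiased_over_replicates(self):
        # mean estimate within 1% of the planted truth over 200 retinas
        totals, truths = [], []
        for seed in range(200):
            sites, ledger = syn.make_retina(
                30_000, 2.0, 9_000, seed=seed, subsample=False)
            totals.append(total_population(sites, "ganglion"))
            truths.append(ledger.truths["true_total_population"])
        assert abs(np.mean(totals) / np.mean(truths) - 1) < 0.01


class TestScheafferCE:
    def test_constant_counts_give_zero(self):
        assert scheaffer_ce([7, 7, 7, 7]) == 0.0

    def test_matches_direct_formula_evaluation(self):
        # independent oracle: textbook ratio-estimator expression
        q = np.arange(1.0, 11.0)
        n, total = len(q), q.sum()
        expected = math.sqrt(n / (n - 1) * (np.sum(q ** 2) / total ** 2 - 1 / n))
        assert scheaffer_ce(q) == pytest.approx(expected, rel=1e-12)

    def test_paper_like_sampling_is_adequate(self):
        # ~200 systematic sites across a streaky retina: CE below 0.1
        sites, _ = syn.make_retina(38_643, 3.0, 8_000, seed=5,
                                   grid_step_mm=0.55, subsample=False)
        counts = [s.counts["ganglion"] for s in sites]
        assert len(counts) > 150
        assert scheaffer_ce(counts) < 0.1

    def test_all_zero_series_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            scheaffer_ce([0, 0, 0])

    def test_too_few_sites_error(self):
        with pytest.raises(ValueError, match="3 sites"):
            scheaffer_ce([1, 2])


class TestDensityMap:
    def test_flat_field_map_is_flat_away_from_edges(self):
        sites = flat_sites(10_000)
        outline = elliptical_outline(3.5, 3.5)
        dmap = density_map(sites, "ganglion", outline)
        xx, yy = np.meshgrid(dmap.x, dmap.y)
        interior = (xx ** 2 + yy ** 2) < 2.0 ** 2
        vals = dmap.density[interior & ~np.isnan(dmap.density)]
        assert np.std(vals) / np.mean(vals) < 0.05

    def test_single_hot_site_peaks_at_that_site(self):
        sites = flat_sites(1_000, n_side=10)
        hot = CountingSite(0.5, 0.5, {"ganglion": 200}, 0.0025, 0.5)
        sites.append(hot)
        dmap = density_map(sites, "ganglion", elliptical_outline(3.0, 3.0))
        iy, ix = np.unravel_index(np.nanargmax(dmap.density), dmap.density.shape)
        assert abs(dmap.x[ix] - 0.5) <= 0.3 and abs(dmap.y[iy] - 0.5) <= 0.3

    def test_mass_conservation_within_five_percent(self):
        sites, _ = syn.make_retina(35_000, 2.5, 9_000, seed=9, subsample=False)
        dmap = density_map(sites, "ganglion", elliptical_outline())
        total = total_population(sites, "ganglion")
        assert dmap.integral() == pytest.approx(total, rel=0.05)

    def test_degenerate_outline_errors(self):
        sites = flat_sites(10_000)
        with pytest.raises(ValueError, match="degenerate"):
            density_map(sites, "ganglion", [(0, 0), (1, 1), (2, 2)])

    def test_needs_ten_sites(self):
        with pytest.raises(ValueError, match="at least 10"):
            density_map(flat_sites(1000, n_side=2)[:4], "ganglion",
                        elliptical_outline())

    def test_streak_top_decile_forms_elongated_band(self):
        # planted horizontal streak: top-decile raster cells span a region
        # much wider (x) than tall (y)
        sites, _ = syn.make_retina(38_000, 4.0, 6_000, seed=21, subsample=False)
        dmap = density_map(sites, "ganglion", elliptical_outline())
        flat = dmap.density[~np.isnan(dmap.density)]
        cut = np.quantile(flat, 0.9)
        yy, xx = np.where(dmap.density >= cut)
        width = dmap.x[xx].max() - dmap.x[xx].min()
        height = dmap.y[yy].max() - dmap.y[yy].min()
        assert width / height > 2


class TestPeakDensity:
    def test_planted_peak_recovered_within_poisson_error(self):
        sites, ledger = syn.make_retina(38_643, 3.0, 8_000, seed=2)
        est = peak_density(sites, "ganglion")
        truth = ledger.truths["true_peak_density"]
        frame = ledger.truths["frame_area_mm2"]
        # site density s.e. under Poisson counting, allowing max-statistic bias
        se_site = math.sqrt(truth * frame) / frame
        assert abs(est - truth) < 4 * se_site

    def test_monotone_field_peaks_at_boundary_site(self):
        step, frame = 0.5, 0.0025
        sites = [CountingSite(x * step, 0.0, {"ganglion": 10 + 5 * x}, frame, step)
                 for x in range(10)]
        best = max(sites, key=lambda s: site_density(s, "ganglion"))
        assert peak_density(sites, "ganglion") == site_density(best, "ganglion")
        assert best.x_mm == max(s.x_mm for s in sites)

    def test_flat_field_peak_close_to_mean(self):
        sites = flat_sites(20_000)
        densities = [site_density(s, "ganglion") for s in sites]
        assert peak_density(sites, "ganglion") == pytest.approx(np.mean(densities))


class TestSpatialResolvingPower:
    def test_quadrupling_density_doubles_srp(self):
        a = spatial_resolving_power(10_000, 1.5)
        b = spatial_resolving_power(40_000, 1.5)
        assert b.srp_cpd == pytest.approx(2 * a.srp_cpd)

    def test_srp_increases_with_lens_radius(self):
        radii = [0.8, 1.2, 1.6, 2.0]
        srps = [spatial_resolving_power(38_000, r).srp_cpd for r in radii]
        assert all(s2 > s1 for s1, s2 in zip(srps, srps[1:]))

    def test_focal_length_uses_matthiessen_ratio(self):
        est = spatial_resolving_power(38_000, 1.5)
        assert est.focal_length_mm == pytest.approx(2.55 * 1.5)

    def test_round_trip_inversion_recovers_inputs(self):
        for d, r in [(37_161, 1.31), (38_643, 1.55), (40_125, 1.79)]:
            srp = spatial_resolving_power(d, r).srp_cpd
            assert lens_radius_for_srp(srp, d) == pytest.approx(r, rel=1e-9)

    def test_printed_acuity_endpoints_imply_plausible_lens_radii(self):
        # peak densities 37,161-40,125 cells/mm² with SRP endpoints 6.4 and
        # 7.2 cpd: the implied lens radius lies in 1.3-1.8 mm and reinserting
        # it reproduces the endpoint
        for srp_target, dens in [(6.4, 37_161.0), (7.2, 40_125.0)]:
            r = lens_radius_for_srp(srp_target, dens)
            assert 1.3 <= r <= 1.8
            assert spatial_resolving_power(dens, r).srp_cpd == \
                pytest.approx(srp_target, rel=1e-9)

    def test_amacrine_correction_scales_density(self):
        full = spatial_resolving_power(38_000, 1.5)
        corrected = spatial_resolving_power(38_000, 1.5, density_correction=0.76)
        assert corrected.srp_cpd == pytest.approx(full.srp_cpd * math.sqrt(0.76))

    def test_nonpositive_inputs_error(self):
        with pytest.raises(ValueError):
            spatial_resolving_power(0, 1.5)
        with pytest.raises(ValueError):
            spatial_resolving_power(38_000, -1)


class TestConeMosaic:
    def test_double_to_single_ratio_is_exactly_two(self):
        singles, doubles = cone_mosaic_counts(10)
        assert doubles / singles == 2.0

    @pytest.mark.parametrize("n", [1, 3, 7])
    def test_ratio_holds_for_any_lattice_size(self, n):
        singles, doubles = cone_mosaic_counts(n)
        assert singles == n * n and doubles == 2 * n * n
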