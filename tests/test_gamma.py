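"""DTA, composite pass rate and gamma index: identities, closed forms, oracles."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import beamcheck as bc
from beamcheck.errors import DataError
from beamcheck.gamma import (Criteria, composite_pass_rate, dta_mm, gamma_map,
                             gamma_map_bruteforce, planar_comparison)


def _smooth_plane(seed, shape=(30, 30), scale=2.0, spacing=1.0):
    rng = np.random.default_rng(seed)
    vals = gaussian_filter(rng.random(shape), 3) * scale + 0.2
    return bc.DoseGrid((0.0, 0.0), (spacing, spacing), vals)


def _flat_plane(value, shape=(30, 30)):
    return bc.DoseGrid((0.0, 0.0), (1.0, 1.0), np.full(shape, value))


def _norm_profile(params, depth=50.0, field=100.0, **pert):
    prof = bc.make_profile(params, field_x=field, depth=depth)
    if pert:
        prof = bc.perturb_curve(prof, bc.Perturbation(**pert))
    return bc.normalize_profile(bc.resample(prof, 1.0))


class TestDta:
    def test_point_on_curve_is_zero(self, profile6):
        assert dta_mm(10.0, profile6.value_at(10.0), profile6) == 0.0

    def test_linear_edge_geometry(self):
        # steep linear edge through x=0: value 100 at x<=-5 falling to 0 at x=5
        x = np.arange(-20.0, 21.0)
        v = np.clip(50.0 - 10.0 * x, 0.0, 100.0)
        edge = bc.ScanCurve(axis="crossline", positions=x, values=v,
                            energy_label="6x", field_x=10, field_y=10,
                            scan_depth=0.0)
        assert dta_mm(2.0, 50.0, edge) == pytest.approx(2.0, abs=1e-6)

    def test_no_match_within_cap_is_infinite(self, profile6):
        assert dta_mm(0.0, 500.0, profile6, search_cap=6.0) == np.inf

    def test_matches_exhaustive_fine_grid_search(self, params6):
        ref = _norm_profile(params6)
        rng = np.random.default_rng(12)
        # independent oracle: dense 0.01 mm evaluation, scan for sign changes
        fine = np.arange(ref.positions[0], ref.positions[-1], 0.01)
        fine_v = np.interp(fine, ref.positions, ref.values)
        for _ in range(200):
            p = rng.uniform(-70, 70)
            v = rng.uniform(1.0, 110.0)
            d = fine_v - v
            hits = np.abs(fine[np.nonzero((d[:-1] * d[1:] <= 0))[0]] - p)
            expected = hits.min() if hits.size else np.inf
            got = dta_mm(p, v, ref)
            if np.isinf(expected):
                assert np.isinf(got)
            else:
                assert got == pytest.approx(expected, abs=0.02)

    def test_2d_step_edge(self):
        vals = np.zeros((21, 21))
        vals[:, 11:] = 1.0  # edge between columns 10 and 11 (x = 10.5)
        grid = bc.DoseGrid((0.0, 0.0), (1.0, 1.0), vals)
        d = dta_mm((10.0, 5.0), 0.5, grid, search_cap=10.0)
        assert d == pytest.approx(5.5, abs=0.1)


class TestCompositePassRate:
    def test_identity_passes_everywhere(self, profile6):
        regions = bc.segment_profile(profile6)
        rate = composite_pass_rate(profile6, profile6,
                                   (regions.penumbra_left, regions.penumbra_right),
                                   Criteria(2, 2))
        assert rate == 1.0

    def test_shift_under_distance_tolerance_passes(self, params6):
        ref = _norm_profile(params6)
        shifted = _norm_profile(params6, lateral_shift=1.9)
        regions = bc.segment_profile(ref)
        rate = composite_pass_rate(ref, shifted,
                                   (regions.penumbra_left, regions.penumbra_right),
                                   Criteria(2, 2))
        assert rate == 1.0

    def test_flat_region_5pct_off_fails(self):
        # flat curve at 100 with a far-away gradient; test is 5% hot
        x = np.arange(-50.0, 51.0)
        v = np.where(x > 40, 100.0 - 20.0 * (x - 40), 100.0).clip(0.1)
        ref = bc.ScanCurve(axis="crossline", positions=x, values=v,
                           energy_label="6x", field_x=100, field_y=100,
                           scan_depth=0.0)
        test = ref.with_data(x, v * 1.05)
        rate = composite_pass_rate(ref, test, (-30.0, 30.0), Criteria(2, 2))
        assert rate == 0.0

    def test_empty_region_rejected(self, profile6):
        with pytest.raises(DataError):
            composite_pass_rate(profile6, profile6, (0.25, 0.35), Criteria(2, 2))

    def test_composite_pass_implied_by_gamma(self, params6):
        """OR-test pass rate dominates the gamma<=1 pass rate."""
        ref = _norm_profile(params6)
        regions = bc.segment_profile(ref)
        region = (regions.penumbra_left, regions.penumbra_right)
        for seed in range(5):
            test = _norm_profile(params6, lateral_shift=0.8, output_scale=1.015,
                                 noise_sd=0.8, seed=seed)
            comp = composite_pass_rate(ref, test, region, Criteria(2, 2))
            gam = composite_pass_rate(ref, test, region, Criteria(2, 2),
                                      method="gamma")
            assert comp >= gam


class TestGammaMap:
    def test_identity_gamma_zero(self):
        plane = _smooth_plane(0)
        result = gamma_map(plane, plane, Criteria(3, 3, "global_max"))
        assert np.nanmax(result.gamma_values) == 0.0
        assert result.pass_fraction == 1.0

    def test_flat_plane_closed_form(self):
        ref = _flat_plane(2.0)
        r3 = gamma_map(ref, _flat_plane(2.0 * 1.03), Criteria(3, 3, "global_max"))
        np.testing.assert_allclose(r3.gamma_values, 1.0, atol=0.01)
        r5 = gamma_map(ref, _flat_plane(2.0 * 1.05), Criteria(3, 3, "global_max"))
        np.testing.assert_allclose(r5.gamma_values, 5.0 / 3.0, atol=0.01)
        assert r5.pass_fraction == 0.0

    @pytest.mark.parametrize("norm", ["global_max", "local", "global_cax"])
    def test_matches_bruteforce_oracle(self, norm):
        ref = _smooth_plane(1)
        ev_vals = ref.values * (1 + 0.03 * gaussian_filter(
            np.random.default_rng(2).standard_normal(ref.values.shape), 4))
        ev = bc.DoseGrid(ref.origin, ref.spacing, np.abs(ev_vals))
        crit = Criteria(3, 3, norm)
        fast = gamma_map(ref, ev, crit)
        brute = gamma_map_bruteforce(ref, ev, crit)
        np.testing.assert_allclose(fast.gamma_values, brute.gamma_values,
                                   atol=1e-6)
        assert fast.pass_fraction == brute.pass_fraction

    def test_gamma_bounded_by_dose_term(self, params6):
        """Distance search can only lower gamma below |dD|/dose_tol."""
        ref = _norm_profile(params6)
        test = _norm_profile(params6, output_scale=1.02, noise_sd=1.0, seed=5)
        crit = Criteria(2, 2, "global_cax")
        result = gamma_map(ref, test, crit)
        bound = np.abs(test.values - np.interp(test.positions, ref.positions,
                                               ref.values)) / crit.dose_tol
        assert np.all(result.gamma_values <= bound + 1e-9)

    def test_pure_shift_gamma_bound(self, params6):
        shift = 1.5
        ref = _norm_profile(params6)
        shifted = _norm_profile(params6, lateral_shift=shift)
        crit = Criteria(2, 2, "global_cax")
        result = gamma_map(ref, shifted, crit, subsample=0.1)
        regions = bc.segment_profile(ref)
        mask = (shifted.positions >= regions.infield[0]) & \
               (shifted.positions <= regions.infield[1])
        assert np.max(result.gamma_values[mask]) <= shift / crit.dist_tol + 0.1

    def test_low_dose_cutoff_excludes_points(self):
        rect = bc.FluenceRect(center=(0.0, 0.0), size=(20.0, 20.0), amplitude=2.0)
        ref = bc.make_dose_plane([rect], spacing=2.0, extent=60.0, smooth_sigma=3.0)
        result = gamma_map(ref, ref, Criteria(3, 3, "global_max"),
                           low_dose_cutoff=50.0)
        assert result.n_evaluated < ref.values.size
        assert np.isnan(result.gamma_values).sum() == \
            ref.values.size - result.n_evaluated

    def test_disjoint_grids_rejected(self):
        a = _smooth_plane(4)
        b = bc.DoseGrid((1000.0, 1000.0), (1.0, 1.0), a.values)
        with pytest.raises(DataError):
            gamma_map(a, b, Criteria(3, 3, "global_max"))

    def test_3d_identity(self):
        rng = np.random.default_rng(6)
        vol = bc.DoseGrid((0, 0, 0), (2.0, 2.0, 2.0),
                          gaussian_filter(rng.random((8, 8, 8)), 1) + 0.1)
        result = gamma_map(vol, vol, Criteria(3, 3, "global_max"))
        assert np.nanmax(result.gamma_values) == 0.0


class TestPlanarComparison:
    def test_identical_planes_pass(self):
        plane = _smooth_plane(7)
        result, ok = planar_comparison(plane, plane, Criteria(3, 3, "global_max"))
        assert ok and result.pass_fraction == 1.0

    def test_5pct_flat_plane_fails_clinical(self):
        ref = _flat_plane(2.0)
        _, ok = planar_comparison(ref, _flat_plane(2.1), Criteria(3, 3, "global_max"))
        assert not ok

    def test_strict_threshold_single_bad_pixel(self):
        ref = _flat_plane(2.0)
        vals = ref.values.copy()
        vals[15, 15] *= 1.5
        _, ok = planar_comparison(ref, bc.DoseGrid(ref.origin, ref.spacing, vals),
                                  Criteria(3, 3, "global_max"),
                                  pass_threshold=100.0)
        assert not ok
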