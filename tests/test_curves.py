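"""Resampling, normalization, PDD error and profile segmentation metrics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beamcheck as bc
from beamcheck.curves import AnalysisConfig, field_label, pool_differences
from beamcheck.errors import DataError


def _profile(positions, values, field=100.0, ssd=1000.0, depth=0.0):
    return bc.ScanCurve(axis="crossline", positions=positions, values=values,
                        energy_label="6x", field_x=field, field_y=field,
                        ssd=ssd, scan_depth=depth)


class TestResample:
    def test_linearity(self):
        c = _profile([0.0, 10.0], [0.0, 10.0])
        out = bc.resample(c, 1.0)
        np.testing.assert_allclose(out.positions, np.arange(11.0))
        np.testing.assert_allclose(out.values, np.arange(11.0))

    def test_idempotence_on_grid(self, profile6):
        out = bc.resample(profile6, 1.0)
        np.testing.assert_allclose(out.values, profile6.values, atol=1e-12)
        again = bc.resample(out, 1.0)
        np.testing.assert_array_equal(again.positions, out.positions)
        np.testing.assert_allclose(again.values, out.values, atol=1e-12)

    def test_step_larger_than_extent_rejected(self):
        c = _profile([0.0, 5.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            bc.resample(c, 10.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(3, 30), st.floats(0.3, 4.0), st.integers(0, 2**31 - 1))
    def test_grid_spacing_property(self, n, step, seed):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.uniform(0.5, 3.0, n))
        c = _profile(pos - pos[n // 2], rng.uniform(1, 100, n))
        if step > c.extent[1] - c.extent[0]:
            return
        out = bc.resample(c, step)
        assert np.allclose(np.diff(out.positions), step)
        assert out.positions[0] == c.positions[0]
        assert out.positions[-1] <= c.positions[-1] + 1e-9


class TestNormalizePdd:
    def test_scales_to_100_and_reports_depth(self, params6):
        pdd = bc.make_pdd(params6)
        doubled = pdd.with_data(pdd.positions, pdd.values * 2.0)
        norm, dmax = bc.normalize_pdd(doubled)
        assert norm.values.max() == pytest.approx(100.0)
        assert dmax == pdd.positions[np.argmax(pdd.values)]

    def test_idempotent(self, params6):
        norm, _ = bc.normalize_pdd(bc.make_pdd(params6))
        again, _ = bc.normalize_pdd(norm)
        np.testing.assert_allclose(again.values, norm.values, atol=1e-12)

    def test_tie_breaks_toward_shallowest(self):
        c = bc.ScanCurve(axis="depth", positions=[0.0, 10.0, 20.0, 30.0],
                         values=[50.0, 80.0, 80.0, 40.0], energy_label="6x",
                         field_x=100, field_y=100)
        _, dmax = bc.normalize_pdd(c)
        assert dmax == 10.0

    def test_dmax_matches_analytic_argmax(self, params6):
        step = 1.0
        pdd = bc.resample(bc.make_pdd(params6), step)
        _, dmax = bc.normalize_pdd(pdd)
        assert abs(dmax - params6.analytic_peak_depth) <= step

    def test_profile_rejected(self, profile6):
        with pytest.raises(ValueError):
            bc.normalize_pdd(profile6)


class TestNormalizeProfile:
    def test_triangle_peak_to_100(self):
        c = _profile([-10.0, 0.0, 10.0], [10.0, 50.0, 10.0])
        out = bc.normalize_profile(c)
        assert out.value_at(0.0) == pytest.approx(100.0)

    def test_offcenter_grid_uses_interpolation(self):
        pos = np.arange(-10.5, 10.0, 1.0)  # no sample at exactly 0
        vals = 100.0 - np.abs(pos)
        c = _profile(pos, vals)
        out = bc.normalize_profile(c)
        # hand interpolation: bracketing samples at -0.5 and +0.5 -> CAX 99.5
        expected = vals * 100.0 / 99.5
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_zero_cax_rejected(self):
        c = _profile([-1.0, 0.0, 1.0], [1.0, 0.0, 1.0])
        with pytest.raises(DataError):
            bc.normalize_profile(c)

    def test_cax_outside_extent_rejected(self):
        c = _profile([5.0, 6.0, 7.0], [1.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            bc.normalize_profile(c)


def _norm_pdd(params, **kw):
    curve, _ = bc.normalize_pdd(bc.resample(bc.make_pdd(params, **kw), 1.0))
    return curve


class TestMeanPddError:
    def test_identity_is_zero(self, params6):
        ref = _norm_pdd(params6)
        s = bc.mean_pdd_error(ref, ref)
        assert s.mean_diff == 0.0 and s.sd_diff == 0.0

    def test_constant_offset(self, params6):
        ref = _norm_pdd(params6)
        test = ref.with_data(ref.positions, ref.values + 1.0)
        s = bc.mean_pdd_error(ref, test)
        assert s.mean_diff == pytest.approx(1.0) and s.sd_diff == pytest.approx(0.0)

    def test_scaled_curve_matches_bruteforce_summation(self, params6):
        ref = _norm_pdd(params6)
        test = ref.with_data(ref.positions, ref.values * 1.01)
        s = bc.mean_pdd_error(ref, test)
        # independent oracle: explicit loop over the window
        dmax = ref.positions[np.argmax(ref.values)]
        diffs = [0.01 * v for z, v in zip(ref.positions, ref.values)
                 if dmax <= z <= 250.0]
        assert s.n_points == len(diffs)
        assert s.mean_diff == pytest.approx(np.mean(diffs), abs=1e-12)
        assert s.sd_diff == pytest.approx(np.std(diffs, ddof=1), abs=1e-12)

    def test_insufficient_coverage_raises(self, params6):
        ref = _norm_pdd(params6)
        short = _norm_pdd(params6, z_max=180.0)
        with pytest.raises(DataError, match="window"):
            bc.mean_pdd_error(ref, short)
        with pytest.raises(DataError):
            bc.mean_pdd_error(short, ref)

    def test_antisymmetry(self, params6):
        ref = _norm_pdd(params6)
        test, _ = bc.normalize_pdd(bc.resample(bc.make_pdd(
            dataclasses.replace(params6, attenuation_mu=1.02 * params6.attenuation_mu)),
            1.0))
        fwd = bc.mean_pdd_error(ref, test)
        # swap roles: window start moves to the other curve's Dmax, so align first
        rev = bc.mean_pdd_error(test, ref)
        assert fwd.mean_diff == pytest.approx(-rev.mean_diff, abs=0.02)
        assert fwd.sd_diff == pytest.approx(rev.sd_diff, abs=0.02)


class TestProjectedWidth:
    @pytest.mark.parametrize("w,ssd,d,expected", [
        (100.0, 1000.0, 0.0, 100.0),
        (100.0, 1000.0, 100.0, 110.0),
        (40.0, 900.0, 50.0, 40.0 * 950.0 / 900.0),
    ])
    def test_similar_triangles(self, w, ssd, d, expected):
        assert bc.projected_field_width(w, ssd, d) == pytest.approx(expected)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            bc.projected_field_width(0.0, 1000.0, 10.0)
        with pytest.raises(ValueError):
            bc.projected_field_width(100.0, 1000.0, -1.0)


class TestEdgesAndSegmentation:
    def test_trapezoid_levels(self, trapezoid):
        assert bc.find_edge_positions(trapezoid, 20.0) == pytest.approx((-48.0, 48.0))
        assert bc.find_edge_positions(trapezoid, 80.0) == pytest.approx((-42.0, 42.0))

    def test_erf_profile_50pct_at_projected_halfwidth(self, params6):
        clean = dataclasses.replace(params6, tail_fraction=0.0, horn_amplitude=0.0)
        prof = bc.normalize_profile(bc.resample(
            bc.make_profile(clean, field_x=100.0, depth=100.0), 1.0))
        left, right = bc.find_edge_positions(prof, 50.0)
        assert right == pytest.approx(55.0, abs=0.05)
        assert left == pytest.approx(-55.0, abs=0.05)

    def test_flat_curve_has_no_crossing(self):
        c = _profile(np.arange(-50.0, 51.0), np.full(101, 100.0))
        with pytest.raises(DataError, match="left|right"):
            bc.find_edge_positions(c, 50.0)

    def test_infield_is_central_80pct_of_projected_width(self, params6):
        prof = bc.normalize_profile(bc.resample(
            bc.make_profile(params6, field_x=100.0, depth=100.0), 1.0))
        regions = bc.segment_profile(prof)
        assert regions.projected_width == pytest.approx(110.0)
        assert regions.infield == pytest.approx((-44.0, 44.0))

    def test_trapezoid_regions(self, trapezoid):
        regions = bc.segment_profile(trapezoid)
        assert regions.penumbra_right == pytest.approx((42.0, 48.0))
        assert regions.penumbra_left == pytest.approx((-48.0, -42.0))
        assert regions.tail_right == pytest.approx((48.0, 63.0))
        assert regions.tail_left == pytest.approx((-63.0, -48.0))

    def test_mlc_smallfield_uses_mlc_width(self, params6):
        prof = bc.make_profile(params6, field_x=20.0, depth=50.0,
                               collimation="mlc")
        prof = bc.normalize_profile(bc.resample(prof, 1.0))
        regions = bc.segment_profile(prof)
        # in-field from the 2 cm MLC aperture, not any jaw setting
        assert regions.infield == pytest.approx((-8.4, 8.4))

    def test_1x1_field_is_all_gradient(self, params6):
        """In a 1x1 cm field the 80% level falls inside the central-80% window."""
        prof = bc.make_profile(params6, field_x=10.0, depth=50.0,
                               collimation="mlc")
        prof = bc.normalize_profile(bc.resample(prof, 1.0))
        regions = bc.segment_profile(prof)
        assert regions.overlaps_infield
        with pytest.raises(DataError):
            regions.validate_strict()

    def test_extent_too_short_for_tails(self, params6):
        prof = bc.make_profile(params6, field_x=100.0, depth=0.0, extent=62.0)
        prof = bc.normalize_profile(bc.resample(prof, 1.0))
        with pytest.raises(DataError, match="tail"):
            bc.segment_profile(prof)

    def test_segmentation_invariant_to_value_rescaling(self, params6):
        raw = bc.make_profile(params6, field_x=100.0, depth=100.0)
        scaled = raw.with_data(raw.positions, raw.values * 7.3)
        r1 = bc.segment_profile(bc.normalize_profile(bc.resample(raw, 1.0)))
        r2 = bc.segment_profile(bc.normalize_profile(bc.resample(scaled, 1.0)))
        assert r1.penumbra_right == pytest.approx(r2.penumbra_right, abs=1e-9)
        assert r1.infield == pytest.approx(r2.infield)


class TestRegionDifferences:
    def test_identity_and_offset(self, profile6):
        regions = bc.segment_profile(profile6)
        zeros = bc.infield_difference(profile6, profile6, regions)
        assert np.all(zeros == 0.0)
        shifted = profile6.with_data(profile6.positions, profile6.values + 1.0)
        ones = bc.infield_difference(profile6, shifted, regions)
        np.testing.assert_allclose(ones, 1.0)

    def test_pooled_count_matches_explicit_count(self, params6):
        diffs, counts = [], []
        for depth in (15.0, 50.0, 100.0, 220.0):
            ref = bc.normalize_profile(bc.resample(
                bc.make_profile(params6, field_x=100.0, depth=depth), 1.0))
            regions = bc.segment_profile(ref)
            d = bc.infield_difference(ref, ref, regions)
            diffs.append(d)
            lo, hi = regions.infield
            counts.append(int(np.sum((ref.positions >= lo - 1e-9)
                                     & (ref.positions <= hi + 1e-9))))
        pooled = pool_differences(diffs, "10x10")
        assert pooled.n_points == sum(counts)

    def test_tail_sample_count_on_exact_grid(self, trapezoid):
        regions = bc.segment_profile(trapezoid)
        d = bc.tail_difference(trapezoid, trapezoid, regions)
        # 15 mm tails on a 1 mm grid, closed intervals: 16 points per side
        assert d.size == 2 * 16

    def test_raised_tail_fraction_shifts_tail_mean_by_one_point(self, params6):
        base = dataclasses.replace(params6, horn_amplitude=0.0)
        bumped = dataclasses.replace(base, tail_fraction=base.tail_fraction + 0.01)
        ref = bc.normalize_profile(bc.resample(
            bc.make_profile(base, field_x=100.0, depth=100.0), 1.0))
        test = bc.normalize_profile(bc.resample(
            bc.make_profile(bumped, field_x=100.0, depth=100.0,
                            extent=ref.positions[-1]), 1.0))
        regions = bc.segment_profile(ref)
        mean_tail = np.mean(bc.tail_difference(ref, test, regions))
        assert mean_tail == pytest.approx(1.0, abs=0.15)

    def test_antisymmetry_under_swap(self, params6):
        ref = bc.normalize_profile(bc.resample(
            bc.make_profile(params6, field_x=100.0, depth=100.0), 1.0))
        pert = bc.perturb_curve(ref, bc.Perturbation(noise_sd=0.5, seed=9))
        test = bc.normalize_profile(pert)
        regions = bc.segment_profile(ref)
        fwd = bc.infield_difference(ref, test, regions)
        rev = bc.infield_difference(test, ref, regions)
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)
        assert np.std(fwd, ddof=1) == pytest.approx(np.std(rev, ddof=1))

    def test_empty_region_rejected(self, profile6):
        regions = bc.segment_profile(profile6)
        tiny = dataclasses.replace(regions)
        with pytest.raises(DataError):
            bc.infield_difference(
                profile6.with_data(profile6.positions, profile6.values),
                profile6, dataclasses.replace(regions, infield=(0.3, 0.4)))


class TestAnalysisConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = AnalysisConfig(resample_step=0.5, planar_pass_threshold=95.0)
        path = cfg.to_yaml(tmp_path / "cfg.yaml")
        back = AnalysisConfig.from_yaml(path)
        assert back == cfg

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            AnalysisConfig(infield_fraction=1.2)
        with pytest.raises(ValueError):
            AnalysisConfig(penumbra_criteria=(0.0, 2.0))

    def test_field_label_format(self, profile6):
        assert field_label(profile6) == "10x10"
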