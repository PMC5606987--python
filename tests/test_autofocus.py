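"""Autofocus search, ETL-1 limits, calibration, and the two scan modes."""

import numpy as np
import pytest

import cdslm as c
from cdslm.autofocus import (CalibrationCurve, CalibrationPoint,
                             PatternNotFoundError, SearchConfig,
                             build_calibration, cdslm_scan,
                             coarse_focus_search, determine_etl1_limits,
                             fine_focus_search, interpolate_calibration,
                             standard_scan)
from cdslm.scope import DomainError


def make_acquire(scope, z, structured, seed0=100):
    counter = [0]

    def acquire(offset):
        counter[0] += 1
        rec = scope.acquire(z, offset, seed=seed0 + counter[0])
        return rec.structured if structured else rec.uniform

    return acquire


class TestCoarseSearch:
    def test_recovers_true_offset_region(self, foam_scope):
        z = 120.0
        true = foam_scope.true_focus_offset(z)  # 54 um
        candidates = np.arange(-300.0, 301.0, 30.0)
        best = coarse_focus_search(make_acquire(foam_scope, z, True),
                                   candidates,
                                   foam_scope.known_modulation_frequency)
        assert abs(best - true) <= 30.0

    def test_matched_sample_picks_zero(self, matched_scope):
        candidates = np.arange(-90.0, 91.0, 30.0)
        best = coarse_focus_search(make_acquire(matched_scope, 90.0, True),
                                   candidates,
                                   matched_scope.known_modulation_frequency)
        assert best == pytest.approx(0.0, abs=30.0)

    def test_dark_sample_raises(self):
        vol = c.SpecimenVolume(np.zeros((16, 32, 32)), (1, 1, 3))
        scope = c.VirtualScope(vol, profile=c.RefractiveIndexProfile.matched())
        with pytest.raises(PatternNotFoundError):
            coarse_focus_search(make_acquire(scope, 24.0, True),
                                np.arange(-30.0, 31.0, 15.0),
                                scope.known_modulation_frequency)

    def test_requires_three_candidates(self, foam_scope):
        with pytest.raises(DomainError):
            coarse_focus_search(make_acquire(foam_scope, 90.0, True),
                                [0.0, 10.0], 0.0625)


class TestFineSearch:
    def test_refines_within_fine_step(self, foam_scope):
        z = 117.0
        true = foam_scope.true_focus_offset(z)
        cfg = SearchConfig(fine_range_um=30.0, fine_step_um=3.0)
        refined = fine_focus_search(make_acquire(foam_scope, z, False),
                                    round(true / 15.0) * 15.0, cfg)
        assert abs(refined - true) <= 3.0

    def test_deterministic_given_seeds(self, foam_scope):
        cfg = SearchConfig()
        a = fine_focus_search(make_acquire(foam_scope, 90.0, False), 40.0, cfg)
        b = fine_focus_search(make_acquire(foam_scope, 90.0, False), 40.0, cfg)
        assert a == b

    def test_flat_metric_prefers_smallest_absolute_offset(self):
        cfg = SearchConfig(fine_range_um=6.0, fine_step_um=3.0)
        with pytest.warns(RuntimeWarning):
            best = fine_focus_search(lambda off: np.ones((16, 16)), 0.0, cfg)
        assert best == 0.0


@pytest.fixture(scope="module")
def sweep():
    # short Rayleigh length: waist position visibly modulates the
    # per-column signal across the field
    vol = c.SpecimenVolume(np.full((24, 48, 96), 10.0), (1, 1, 2))
    sheet = c.LightSheetModel(waist_fwhm_um=2.0)
    scope = c.VirtualScope(vol, sheet,
                           c.DetectionModel(image_shape=(48, 96)),
                           c.RefractiveIndexProfile.matched())
    values = np.linspace(0.0, 95.0, 11)
    imgs = [scope.acquire(24.0, 0.0, seed=None, waist_x_um=v).uniform
            for v in values]
    return imgs, values


class TestEtl1Limits:

    def test_limits_bracket_field_edges(self, sweep):
        imgs, values = sweep
        lo, hi = determine_etl1_limits(imgs, values)
        step = values[1] - values[0]
        assert abs(lo - 0.0) <= step
        assert abs(hi - 95.0) <= step

    def test_uniform_images_degenerate_with_warning(self):
        imgs = [np.ones((16, 16))] * 5
        with pytest.warns(RuntimeWarning):
            lo, hi = determine_etl1_limits(imgs, np.arange(5.0))
        assert lo == hi

    def test_too_few_sweep_values_raises(self):
        with pytest.raises(DomainError):
            determine_etl1_limits([np.ones((8, 8))] * 2, [0.0, 1.0])


class TestCalibrationInterpolation:
    @pytest.fixture
    def affine_curve(self):
        pts = [CalibrationPoint(z, 0.45 * z + 10.0, (z, z + 5.0))
               for z in (0.0, 400.0, 1100.0, 2000.0)]
        return CalibrationCurve(pts)

    def test_stored_point_exact(self, affine_curve):
        p = interpolate_calibration(affine_curve, 400.0)
        assert p.focus_offset_um == pytest.approx(0.45 * 400 + 10)

    def test_affine_map_recovered_between_points(self, affine_curve):
        for q in (123.4, 777.0, 1500.5):
            p = interpolate_calibration(affine_curve, q)
            assert p.focus_offset_um == pytest.approx(0.45 * q + 10.0)
            assert p.etl1_limits[0] == pytest.approx(q)

    def test_clamped_beyond_ends(self, affine_curve):
        assert interpolate_calibration(affine_curve, 9999.0).focus_offset_um \
            == pytest.approx(0.45 * 2000 + 10)
        assert interpolate_calibration(affine_curve, -50.0).focus_offset_um \
            == pytest.approx(10.0)

    def test_single_point_curve_rejected(self):
        with pytest.raises(DomainError):
            CalibrationCurve([CalibrationPoint(0.0, 0.0)])

    def test_csv_roundtrip(self, affine_curve, tmp_path):
        affine_curve.to_csv(tmp_path / "cal.csv")
        back = CalibrationCurve.from_csv(tmp_path / "cal.csv")
        np.testing.assert_allclose(back.focus_offset_um,
                                   affine_curve.focus_offset_um)


class TestBuildCalibration:
    def test_mismatched_medium_offsets_track_depth(self, foam_scope):
        curve = build_calibration(foam_scope, [30.0, 90.0, 150.0],
                                  SearchConfig(), seed=4)
        for pt in curve.points:
            assert pt.focus_offset_um == pytest.approx(
                0.45 * pt.sheet_z_um, abs=3.0)

    def test_matched_medium_offsets_near_zero(self, matched_scope):
        curve = build_calibration(matched_scope, [60.0, 120.0],
                                  SearchConfig(), seed=4)
        for pt in curve.points:
            assert abs(pt.focus_offset_um) <= 3.0

    def test_dark_specimen_raises(self):
        vol = c.SpecimenVolume(np.zeros((16, 32, 32)), (1, 1, 3))
        scope = c.VirtualScope(vol, profile=c.RefractiveIndexProfile.matched())
        with pytest.warns(RuntimeWarning):
            with pytest.raises(PatternNotFoundError):
                build_calibration(scope, [12.0, 36.0], SearchConfig(), seed=1)


class TestScans:
    def test_matched_medium_zero_residual(self, matched_scope):
        res = standard_scan(matched_scope, 30.0, 150.0, 30.0,
                            compute_sedct=False)
        assert res.report["residual_um"].max() == pytest.approx(0.0)

    def test_standard_scan_residual_is_index_mismatch_times_depth(
            self, foam_scope):
        res = standard_scan(foam_scope, 0.0, 180.0, 30.0,
                            compute_sedct=False)
        np.testing.assert_allclose(res.report["residual_um"],
                                   0.45 * res.report["z_um"], rtol=1e-9)

    def test_cdslm_scan_residual_bounded_by_calibration(self, foam_scope):
        curve = build_calibration(foam_scope, [30.0, 90.0, 150.0],
                                  SearchConfig(), seed=4)
        res = cdslm_scan(foam_scope, curve, 30.0, 150.0, 15.0, seed=8,
                         compute_sedct=False)
        assert res.report["residual_um"].max() <= 3.0

    def test_identical_seeds_identical_stacks(self, foam_scope):
        a = standard_scan(foam_scope, 30.0, 90.0, 30.0, seed=5,
                          compute_sedct=False)
        b = standard_scan(foam_scope, 30.0, 90.0, 30.0, seed=5,
                          compute_sedct=False)
        np.testing.assert_array_equal(a.uniform, b.uniform)

    def test_nonpositive_step_rejected(self, foam_scope):
        with pytest.raises(DomainError):
            standard_scan(foam_scope, 0.0, 90.0, -3.0)
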