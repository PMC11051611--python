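"""Radiometric calibration, resolution degradation, cross-sensor fitting."""

import numpy as np
import pytest

from alanex.errors import CalibrationError, RasterError
from alanex.nightscape import (
    LinearCalibration,
    NTLRaster,
    SensorSpec,
    apply_calibration,
    calibrate_gain_bias,
    calibrate_power_law,
    degrade_resolution,
    fit_cross_calibration,
    sample_buffer_pairs,
    to_band_radiance,
)

POWER_SENSOR = SensorSpec(name="pan130", nominal_resolution=130.0, bandwidth=520.0,
                          calibration_kind="power_law")
GB_SENSOR = SensorSpec(name="glimmer10", nominal_resolution=10.0, bandwidth=466.0,
                       calibration_kind="gain_bias", gain=0.5, bias=2.0)


def _dn(vals, nodata=-9999.0):
    vals = np.asarray(vals, dtype=float)
    return NTLRaster(vals, origin_x=0.0, origin_y=vals.shape[0] * 10.0, pixel_size=10.0,
                     nodata=nodata, units_tag="DN")


class TestRadiometric:
    def test_power_law_fixed_points(self):
        out = calibrate_power_law(_dn([[0.0, 1.0], [10000.0, 4.0]]), POWER_SENSOR)
        assert out.units_tag == "spectral_radiance"
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == pytest.approx(1e-10)
        # 10000^1.5 / 1e10 evaluated independently: 1e6/1e10 = 1e-4
        assert out.values[1, 0] == pytest.approx(1.0e-4)

    def test_power_law_rejects_negative_dn_and_wrong_units(self):
        with pytest.raises(CalibrationError, match="negative DN"):
            calibrate_power_law(_dn([[-1.0, 2.0]]), POWER_SENSOR)
        ras = _dn([[1.0]])
        ras = ras.with_values(ras.values, units_tag="band_radiance")
        with pytest.raises(CalibrationError, match="units_tag"):
            calibrate_power_law(ras, POWER_SENSOR)

    def test_gain_bias_examples_and_nodata(self):
        out = calibrate_gain_bias(_dn([[0.0, 100.0], [-9999.0, 4.0]]), GB_SENSOR)
        assert out.values[0, 0] == 2.0  # zero DN returns the bias
        assert out.values[0, 1] == 52.0
        assert out.values[1, 0] == -9999.0  # nodata untouched

    def test_gain_bias_requires_coefficients(self):
        with pytest.raises(CalibrationError):
            SensorSpec(name="x", nominal_resolution=10.0, calibration_kind="gain_bias")

    def test_band_radiance_default_factor_and_round_trip(self):
        spec = SensorSpec(name="x", nominal_resolution=10.0, bandwidth=520.0)
        ras = _dn([[0.0, 1.0]]).with_values(np.array([[0.0, 1.0]]),
                                            units_tag="spectral_radiance")
        out = to_band_radiance(ras, spec)
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == pytest.approx(0.52 * 1e5)  # bandwidth(μm) × 1e5
        back = out.with_values(out.values / spec.band_conversion_factor)
        np.testing.assert_allclose(back.values, ras.values, rtol=1e-12)
        with pytest.raises(CalibrationError):
            to_band_radiance(ras, spec, factor=0.0)

    def test_calibration_preserves_dn_ordering(self, rng):
        dn = _dn(rng.uniform(0, 1e4, (16, 16)))
        order = np.argsort(dn.values.ravel())
        for out in (calibrate_power_law(dn, POWER_SENSOR), calibrate_gain_bias(dn, GB_SENSOR)):
            assert (np.argsort(out.values.ravel()) == order).all()


class TestDegrade:
    def test_block_mean_and_constant(self):
        ras = _dn([[1.0, 2.0], [3.0, 4.0]])
        out = degrade_resolution(ras, 2)
        assert out.values.shape == (1, 1)
        assert out.values[0, 0] == pytest.approx(2.5)
        assert out.pixel_size == 20.0
        const = NTLRaster(np.full((8, 8), 7.0), 0, 80, 10)
        np.testing.assert_allclose(degrade_resolution(const, 4).values, 7.0)

    def test_global_mean_preserved(self, random_raster):
        out = degrade_resolution(random_raster, 4)
        assert out.valid_mean() == pytest.approx(random_raster.valid_mean(), rel=1e-9)

    def test_composition_equals_single_step(self, random_raster):
        two_step = degrade_resolution(degrade_resolution(random_raster, 2), 4)
        one_step = degrade_resolution(random_raster, 8)
        np.testing.assert_allclose(two_step.values, one_step.values, rtol=1e-12)

    def test_nodata_blocks_propagate(self):
        vals = np.full((4, 4), 5.0)
        vals[:2, :2] = -9999.0
        vals[2, 2] = -9999.0
        out = degrade_resolution(NTLRaster(vals, 0, 40, 10, nodata=-9999.0), 2)
        assert out.values[0, 0] == -9999.0  # all-nodata block
        assert out.values[1, 1] == 5.0  # partial block ignores nodata

    def test_bad_factor_and_indivisible_grid(self):
        ras = _dn(np.ones((3, 3)))
        with pytest.raises(RasterError):
            degrade_resolution(ras, 0)
        with pytest.raises(RasterError):
            degrade_resolution(ras, 2)
        padded = degrade_resolution(ras, 2, pad="nodata")
        assert padded.values.shape == (2, 2)


class TestCrossCalibration:
    def test_noiseless_affine_recovered_exactly(self):
        x = np.linspace(10, 400, 25)
        pairs = np.stack([2.0 * x + 3.0, x], axis=1)
        cal = fit_cross_calibration(pairs)
        assert cal.slope == pytest.approx(2.0, rel=1e-10)
        assert cal.intercept == pytest.approx(3.0, rel=1e-10)
        assert cal.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_two_se(self, rng):
        """OLS on y = 1.47x + 23.14 + ε recovers the coefficients within 2 SE."""
        x = rng.uniform(50, 400, 300)
        y = 1.47 * x + 23.14 + rng.normal(0, 8.0, 300)
        cal = fit_cross_calibration(np.stack([y, x], axis=1))
        assert abs(cal.slope - 1.47) < 2 * cal.slope_se
        assert abs(cal.intercept - 23.14) < 2 * cal.intercept_se

    def test_degenerate_predictor_rejected(self):
        pairs = np.stack([np.arange(5.0), np.ones(5)], axis=1)
        with pytest.raises(CalibrationError, match="zero variance"):
            fit_cross_calibration(pairs)

    def test_apply_calibration_scalar_array_raster(self):
        cal = LinearCalibration(slope=2.0, intercept=3.0, r2=0.9, n_samples=10)
        assert apply_calibration(0.0, cal) == 3.0
        np.testing.assert_allclose(apply_calibration(np.array([1.0, 2.0]), cal), [5.0, 7.0])
        ras = NTLRaster(np.array([[1.0, -9999.0]]), 0, 10, 10, nodata=-9999.0)
        out = apply_calibration(ras, cal)
        assert out.values[0, 0] == 5.0
        assert out.values[0, 1] == -9999.0  # nodata survives

    def test_affine_inverse_round_trip(self, rng):
        cal = LinearCalibration(slope=1.47, intercept=23.14, r2=0.9, n_samples=10)
        x = rng.uniform(0, 500, 100)
        back = (apply_calibration(x, cal) - cal.intercept) / cal.slope
        np.testing.assert_allclose(back, x, rtol=1e-12)


class TestBufferPairs:
    def test_identity_and_scaled_rasters(self, random_raster):
        pairs = sample_buffer_pairs(random_raster, random_raster, n_points=5,
                                    radius=50.0, seed=3)
        np.testing.assert_allclose(pairs[:, 0], pairs[:, 1])
        doubled = random_raster.with_values(2.0 * random_raster.values)
        pairs2 = sample_buffer_pairs(doubled, random_raster, n_points=5, radius=50.0, seed=3)
        np.testing.assert_allclose(pairs2[:, 0], 2.0 * pairs2[:, 1], rtol=1e-12)

    def test_seed_determinism(self, random_raster):
        a = sample_buffer_pairs(random_raster, random_raster, 6, 40.0, seed=9)
        b = sample_buffer_pairs(random_raster, random_raster, 6, 40.0, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_min_separation_enforced(self, random_raster):
        # only ~4 disjoint discs of radius 150 m fit on a 640 m square
        with pytest.raises(CalibrationError, match="could only place"):
            sample_buffer_pairs(random_raster, random_raster, 50, 150.0, seed=1,
                                min_separation=300.0, max_attempts_factor=5)

    def test_disjoint_rasters_rejected(self, random_raster):
        far = NTLRaster(random_raster.values, origin_x=1e6, origin_y=640.0, pixel_size=10.0)
        with pytest.raises(CalibrationError, match="overlap"):
            sample_buffer_pairs(random_raster, far, 5, 50.0, seed=1)
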