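"""Exposure estimators: point sampling, buffer integrals, MOM/RBM identities."""

import numpy as np
import pytest

from alanex.errors import ExposureError
from alanex.exposure import (
    DiscSampler,
    ExposureSetting,
    HomeLocation,
    buffer_average,
    canonical_settings,
    disc_pixel_weights,
    exposure_matrix,
    mom_buffer,
    mom_in_situ,
    pixel_at,
    rbm_buffer,
    rbm_in_situ,
)
from alanex.mobility import WeightSeries
from alanex.nightscape import LinearCalibration, NTLRaster, degrade_resolution

from conftest import all_night_weights, build_trajectory, supersample_disc_mean

import pandas as pd


class TestPixelAt:
    def test_centre_and_half_open_edges(self, ramp_raster):
        assert pixel_at(ramp_raster, 15.0, 25.0) == 2.0
        # x = 10 is the left (closed) edge of column 1
        assert pixel_at(ramp_raster, 10.0, 25.0) == 2.0
        # y = 20 is the top (closed) edge of row 1
        assert pixel_at(ramp_raster, 5.0, 20.0) == 4.0
        # top-left corner of the raster belongs to pixel (0, 0)
        assert pixel_at(ramp_raster, 0.0, 30.0) == 1.0

    def test_outside_extent_rejected(self, ramp_raster):
        with pytest.raises(ExposureError):
            pixel_at(ramp_raster, 31.0, 15.0)

    def test_nodata_pixel_rejected(self):
        ras = NTLRaster(np.array([[1.0, -9999.0]]), 0, 10, 10, nodata=-9999.0)
        with pytest.raises(ExposureError, match="nodata"):
            pixel_at(ras, 15.0, 5.0)


class TestBufferAverage:
    def test_constant_raster_any_disc(self, flat_raster):
        for r in (4.0, 35.0, 95.0):
            assert buffer_average(flat_raster, 101.0, 99.0, r) == pytest.approx(42.0)

    def test_disc_inside_single_pixel(self, ramp_raster):
        assert buffer_average(ramp_raster, 15.0, 15.0, 4.0) == pytest.approx(5.0)

    def test_matches_supersampling_oracle_on_ramp(self, ramp_raster):
        got = buffer_average(ramp_raster, 15.0, 15.0, 15.0)
        oracle = supersample_disc_mean(ramp_raster, 15.0, 15.0, 15.0, n_side=1500)
        assert got == pytest.approx(oracle, rel=1e-3)

    def test_matches_shapely_polygon_oracle(self, random_raster):
        """Independent geometric route: shapely pixel-box ∩ polygonal disc."""
        from shapely.geometry import Point, box

        cx, cy, radius = 321.0, 287.5, 77.0
        disc = Point(cx, cy).buffer(radius, quad_segs=256)
        p = random_raster.pixel_size
        num = den = 0.0
        nr, nc = random_raster.shape
        for i in range(nr):
            for j in range(nc):
                cell = box(j * p, random_raster.origin_y - (i + 1) * p,
                           (j + 1) * p, random_raster.origin_y - i * p)
                a = disc.intersection(cell).area
                num += a * random_raster.values[i, j]
                den += a
        assert buffer_average(random_raster, cx, cy, radius) == pytest.approx(
            num / den, rel=1e-6)

    def test_area_weights_sum_to_disc_area(self, flat_raster):
        _, _, area = disc_pixel_weights(flat_raster, 100.3, 101.7, 60.0)
        assert area.sum() == pytest.approx(np.pi * 60.0**2, rel=1e-12)

    def test_edge_buffer_renormalizes(self, flat_raster):
        # half the disc hangs off the raster; the mean is still the constant
        assert buffer_average(flat_raster, 0.0, 100.0, 50.0) == pytest.approx(42.0)

    def test_nodata_excluded(self):
        vals = np.full((10, 10), 5.0)
        vals[:, 5:] = -9999.0
        ras = NTLRaster(vals, 0, 100, 10, nodata=-9999.0)
        assert buffer_average(ras, 50.0, 50.0, 30.0) == pytest.approx(5.0)
        with pytest.raises(ExposureError):
            buffer_average(ras, 90.0, 50.0, 20.0)  # fully in the nodata half

    def test_sampler_bit_identical_to_direct(self, random_raster, rng):
        sampler = DiscSampler(random_raster, 47.0)
        for _ in range(20):
            x = rng.uniform(50, 590)
            y = rng.uniform(50, 590)
            assert sampler.mean_at(x, y) == buffer_average(random_raster, x, y, 47.0)


class TestResidenceEstimators:
    def test_in_situ_is_home_pixel(self, ramp_raster):
        res = rbm_in_situ(ramp_raster, HomeLocation(25.0, 5.0), "p1")
        assert res.value == 9.0

    def test_in_situ_after_degradation_is_block_mean(self, random_raster):
        home = HomeLocation(205.0, 411.0)
        deg = degrade_resolution(random_raster, 2)
        row, col = deg.rowcol(home.x_h, home.y_h)
        block = random_raster.values[2 * row:2 * row + 2, 2 * col:2 * col + 2]
        assert rbm_in_situ(deg, home).value == pytest.approx(block.mean(), rel=1e-12)

    def test_tiny_buffer_equals_in_situ(self, ramp_raster):
        home = HomeLocation(15.0, 15.0)
        assert rbm_buffer(ramp_raster, home, 3.0).value == rbm_in_situ(ramp_raster, home).value

    def test_single_bright_pixel_nonincreasing_in_radius(self):
        vals = np.zeros((40, 40))
        vals[20, 20] = 1000.0
        ras = NTLRaster(vals, 0, 400, 10)
        home = HomeLocation(205.0, 195.0)  # inside the bright pixel
        values = [rbm_buffer(ras, home, r).value for r in (6.5, 10, 25, 30, 50)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestMobilityEstimators:
    def test_stationary_all_night_equals_pixel(self, ramp_raster):
        traj = build_trajectory([(15.0, 15.0)] * 30)
        res = mom_in_situ(ramp_raster, traj, all_night_weights(30))
        assert res.value == 5.0
        assert res.night_fraction == 1.0

    def test_equal_time_at_two_values(self):
        vals = np.array([[100.0, 200.0]])
        ras = NTLRaster(vals, 0, 10, 10)
        pos = [(5.0, 5.0)] * 10 + [(15.0, 5.0)] * 10 + [(15.0, 5.0)]
        traj = build_trajectory(pos)
        res = mom_in_situ(ras, traj, all_night_weights(21))
        assert res.value == pytest.approx(150.0)

    def test_daytime_zero_rule_and_night_renormalization(self):
        ras = NTLRaster(np.array([[100.0]]), 0, 10, 10)
        traj = build_trajectory([(5.0, 5.0)] * 21)
        flags = np.zeros(21, dtype=bool)
        flags[:10] = True  # first half of the time is night
        w = np.full(21, 1 / 20)
        w[-1] = 0.0
        ws = WeightSeries(weights=w / w.sum(), night_flags=flags)
        full = mom_in_situ(ras, traj, ws, duration_mode="full")
        renorm = mom_in_situ(ras, traj, ws, duration_mode="night")
        assert full.value == pytest.approx(50.0)
        assert renorm.value == pytest.approx(100.0)

    def test_stationary_mom_buffer_equals_rbm_buffer_bitwise(self, random_raster):
        home = (305.0, 277.5)
        traj = build_trajectory([home] * 50)
        for r in (65.0, 100.0, 250.0):
            mom = mom_buffer(random_raster, traj, r, all_night_weights(50))
            rbm = rbm_buffer(random_raster, HomeLocation(*home), r)
            assert mom.value == rbm.value  # bit-exact degenerate-mobility identity

    def test_refinement_invariance(self, random_raster):
        """Duplicating a fix mid-interval at the same place leaves MOM unchanged."""
        pos = [(100.0, 100.0)] * 10 + [(300.0, 300.0)] * 11
        base = build_trajectory(pos, interval=120.0)
        refined_pos = pos[:5] + [pos[5]] + pos[5:]  # extra fix on the dwell
        refined = build_trajectory(refined_pos, interval=120.0)
        # rebuild times so the inserted fix bisects an interval
        t = base.times
        tt = np.insert(t, 6, (t[5] + t[6]) / 2.0)
        refined.times = tt
        w_base = all_night_weights(len(base))
        w_ref = all_night_weights(len(refined))
        from alanex.mobility import temporal_weights

        w_base = temporal_weights(base)
        w_base.night_flags = np.ones(len(base), dtype=bool)
        w_ref = temporal_weights(refined)
        w_ref.night_flags = np.ones(len(refined), dtype=bool)
        a = mom_in_situ(random_raster, base, w_base).value
        b = mom_in_situ(random_raster, refined, w_ref).value
        assert a == pytest.approx(b, abs=1e-12 * max(1.0, abs(a)))

    def test_convexity_in_night_mode(self, random_raster, rng):
        pos = [(float(rng.uniform(50, 590)), float(rng.uniform(50, 590))) for _ in range(40)]
        traj = build_trajectory(pos)
        res = mom_in_situ(random_raster, traj, all_night_weights(40), duration_mode="night")
        vals = [pixel_at(random_raster, x, y) for x, y in pos]
        assert min(vals) - 1e-9 <= res.value <= max(vals) + 1e-9

    def test_night_fix_outside_extent_rejected(self, ramp_raster):
        traj = build_trajectory([(15.0, 15.0), (500.0, 15.0), (15.0, 15.0)])
        with pytest.raises(ExposureError, match="outside"):
            mom_in_situ(ramp_raster, traj, all_night_weights(3))


class TestSettings:
    def test_canonical_settings_labels(self):
        labels = sorted(s.label for s in canonical_settings())
        assert len(labels) == 20
        for want in ("M_r500m", "M_r500m_CC", "M_r130m", "M_r130m_CC", "M_r010m",
                     "M_b065m", "M_b100m", "M_b250m", "M_b300m", "M_b500m",
                     "R_r500m", "R_b065m"):
            assert want in labels

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ExposureError):
            ExposureSetting("MOM", "buffer", 500.0, radius=100.0)  # buffers are 10 m only
        with pytest.raises(ExposureError):
            ExposureSetting("MOM", "in_situ", 10.0, cross_calibrated=True)
        with pytest.raises(ExposureError):
            ExposureSetting("RBM", "in_situ", 130.0, radius=100.0)


class TestMatrix:
    @pytest.fixture()
    def tiny_world(self, rng):
        rasters = {}
        for com, level in (("old_town", 300.0), ("new_town", 150.0)):
            vals = rng.uniform(0.5, 1.5, (130, 130)) * level
            fine = NTLRaster(vals, 0, 1300, 10)
            rasters[(com, 10.0)] = fine
            rasters[(com, 130.0)] = degrade_resolution(fine, 13)
            rasters[(com, 500.0)] = degrade_resolution(fine, 50, pad="nodata")
        participants = pd.DataFrame({
            "participant_id": ["a", "b", "c", "d"],
            "community": ["old_town", "old_town", "new_town", "new_town"],
            "home_x": [405.0, 610.5, 505.0, 700.0],
            "home_y": [655.0, 810.5, 705.0, 900.0],
        })
        trajectories, weights = {}, {}
        for pid, hx, hy in zip(participants.participant_id, participants.home_x,
                               participants.home_y):
            trajectories[pid] = build_trajectory([(hx, hy)] * 30, participant_id=pid)
            weights[pid] = all_night_weights(30)
        cals = {130.0: LinearCalibration(1.5, 10.0, 0.95, 100),
                500.0: LinearCalibration(2.0, 5.0, 0.9, 100)}
        return participants, trajectories, rasters, cals, weights

    def test_shape_and_labels(self, tiny_world):
        participants, trajectories, rasters, cals, weights = tiny_world
        m = exposure_matrix(participants, trajectories, rasters,
                            calibrations=cals, weights=weights)
        assert len(m) == 4 * 20
        assert m["setting"].nunique() == 20

    def test_stationary_cohort_mom_equals_rbm(self, tiny_world):
        participants, trajectories, rasters, cals, weights = tiny_world
        m = exposure_matrix(participants, trajectories, rasters,
                            calibrations=cals, weights=weights)
        wide = m.pivot_table(index="participant_id", columns="setting", values="value")
        for body in ("r500m", "r130m", "r010m", "b065m", "b100m", "b250m", "b300m", "b500m"):
            np.testing.assert_array_equal(wide[f"M_{body}"], wide[f"R_{body}"])

    def test_cc_columns_are_affine_in_raw(self, tiny_world):
        participants, trajectories, rasters, cals, weights = tiny_world
        m = exposure_matrix(participants, trajectories, rasters,
                            calibrations=cals, weights=weights)
        wide = m.pivot_table(index="participant_id", columns="setting", values="value")
        for res, body in ((130.0, "r130m"), (500.0, "r500m")):
            cal = cals[res]
            for p in ("M", "R"):
                diff = wide[f"{p}_{body}_CC"] - cal.slope * wide[f"{p}_{body}"]
                np.testing.assert_allclose(diff, cal.intercept, rtol=1e-12)

    def test_missing_raster_or_calibration_named(self, tiny_world):
        participants, trajectories, rasters, cals, weights = tiny_world
        bad = dict(rasters)
        del bad[("new_town", 500.0)]
        with pytest.raises(ExposureError, match="M_r500m"):
            exposure_matrix(participants, trajectories, bad,
                            calibrations=cals, weights=weights)
        with pytest.raises(ExposureError, match="no cross-calibration"):
            exposure_matrix(participants, trajectories, rasters,
                            calibrations={}, weights=weights)
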