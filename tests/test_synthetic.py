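"""The synthetic study generator: nightscapes, sensors, trajectories, cohorts."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alanex.errors import AlanexError
from alanex.exposure import HomeLocation
from alanex.nightscape import fit_cross_calibration, sample_buffer_pairs
from alanex.solar import night_windows_for_range
from alanex.synthetic_data import (
    NEW_TOWN,
    OLD_TOWN,
    CommunityArchetype,
    OutcomeModel,
    TrajectoryProfile,
    make_multisensor,
    make_nightscape,
    make_outcomes,
    make_population,
    make_trajectory,
)

WINDOWS = night_windows_for_range(date(2021, 6, 7), 7, 114.1, 22.3, 8.0)


class TestNightscape:
    def test_archetype_means_hit_targets(self):
        old = make_nightscape(OLD_TOWN, 130, 130, seed=1)
        new = make_nightscape(NEW_TOWN, 130, 130, seed=1)
        assert old.valid_mean() == pytest.approx(325.32, rel=0.05)
        assert new.valid_mean() == pytest.approx(210.78, rel=0.05)
        assert (old.values >= 0).all() and (new.values >= 0).all()

    def test_seed_determinism(self):
        a = make_nightscape(OLD_TOWN, 65, 65, seed=7)
        b = make_nightscape(OLD_TOWN, 65, 65, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_archetype_ordering(self):
        for seed in range(5):
            old = make_nightscape(OLD_TOWN, 130, 130, seed=seed)
            new = make_nightscape(NEW_TOWN, 130, 130, seed=seed)
            assert old.valid_mean() > new.valid_mean()

    def test_residential_mask_off_bright_pixels(self):
        ras, mask = make_nightscape(OLD_TOWN, 130, 130, seed=3, with_mask=True)
        assert mask.any()
        # homes sit in the dim part of the scene
        assert ras.values[mask].mean() < ras.valid_mean()

    def test_unattainable_mean_rejected(self):
        bad = CommunityArchetype(name="old_town", target_mean=1e6)
        with pytest.raises(AlanexError, match="unattainable"):
            make_nightscape(bad, 64, 64, seed=0)

    def test_too_small_grid_rejected(self):
        with pytest.raises(AlanexError):
            make_nightscape(OLD_TOWN, 16, 16, seed=0)


class TestMultisensor:
    def test_identity_distortion_recovers_unit_line(self):
        truth = make_nightscape(OLD_TOWN, 650, 650, seed=2)
        ms = make_multisensor(truth, {"mid": (1.0, 0.0, 0.0), "coarse": (1.0, 0.0, 0.0)})
        pairs = sample_buffer_pairs(ms.fine, ms.mid, n_points=40, radius=300.0, seed=5)
        cal = fit_cross_calibration(pairs)
        assert cal.slope == pytest.approx(1.0, abs=0.06)
        # intercept noise trades off against slope; bound it by a few percent
        # of the scene's mean radiance
        assert abs(cal.intercept) < 0.1 * truth.valid_mean()
        assert cal.r2 > 0.98

    def test_resolutions(self):
        truth = make_nightscape(OLD_TOWN, 130, 130, seed=2)
        ms = make_multisensor(truth, seed=1)
        assert ms.mid.pixel_size == 130.0
        assert ms.coarse.pixel_size == 500.0
        assert ms.fine is truth

    def test_noise_monotonically_degrades_r2(self):
        truth = make_nightscape(OLD_TOWN, 650, 650, seed=4)
        r2s = []
        for cv in (0.0, 0.3, 1.0):
            ms = make_multisensor(truth, {"mid": (1.47, 23.14, cv)}, seed=8)
            pairs = sample_buffer_pairs(ms.fine, ms.mid, n_points=40, radius=300.0, seed=5)
            r2s.append(fit_cross_calibration(pairs).r2)
        assert r2s[0] > r2s[1] > r2s[2]


class TestTrajectory:
    def _profile(self, **kw):
        defaults = dict(home=HomeLocation(3000.0, 3000.0), days=2,
                        bounds=(1.0, 1.0, 6499.0, 6499.0))
        defaults.update(kw)
        return TrajectoryProfile(**defaults)

    def test_stationary_when_no_mobility(self):
        prof = self._profile(excursions_per_night=0.0, day_radius=0.0)
        traj = make_trajectory(prof, WINDOWS, seed=1)
        assert np.ptp(traj.x) == 0.0 and np.ptp(traj.y) == 0.0

    def test_night_excursions_within_radius(self):
        from alanex.mobility import night_mask

        prof = self._profile(excursions_per_night=3.0, excursion_radius=400.0, days=7)
        traj = make_trajectory(prof, WINDOWS, seed=2)
        night = night_mask(traj, WINDOWS)
        d = np.hypot(traj.x[night] - 3000.0, traj.y[night] - 3000.0)
        assert d.mean() > 0.0
        assert d.max() <= 400.0 + 100.0  # destination radius + wobble allowance

    def test_one_minute_cadence_and_duration(self):
        prof = self._profile(days=2)
        traj = make_trajectory(prof, WINDOWS, seed=3)
        assert len(traj) == 2 * 1440
        np.testing.assert_allclose(np.diff(traj.times), 60.0)

    def test_seed_determinism(self):
        prof = self._profile(days=1)
        a = make_trajectory(prof, WINDOWS, seed=11)
        b = make_trajectory(prof, WINDOWS, seed=11)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)


class TestPopulation:
    def test_marginals_within_binomial_band(self):
        df = make_population(104, seed=5)
        old = df[df.community == "old_town"]
        share = (old["gender"] == "female").mean()
        # 95% binomial band around the configured 57.7%
        half = 1.96 * np.sqrt(0.577 * 0.423 / 104)
        assert abs(share - 0.577) <= half + 1e-9

    def test_degenerate_spec_all_identical(self):
        spec = {"old_town": {"gender": {"female": 1.0}}}
        df = make_population(20, demographics_spec=spec, seed=1)
        assert (df["gender"] == "female").all()

    def test_bad_proportions_rejected(self):
        spec = {"old_town": {"gender": {"male": 0.7, "female": 0.7}}}
        with pytest.raises(AlanexError, match="sum to 1"):
            make_population(10, demographics_spec=spec, seed=1)

    def test_homes_inside_mask_cells(self):
        ras, mask = make_nightscape(OLD_TOWN, 130, 130, seed=3, with_mask=True)
        df = make_population(50, seed=2, masks={"old_town": (ras, mask),
                                                "new_town": (ras, mask)})
        for hx, hy in zip(df.home_x, df.home_y):
            row, col = ras.rowcol(hx, hy)
            assert mask[row, col]

    def test_seed_determinism(self):
        a = make_population(30, seed=9)
        b = make_population(30, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestOutcomes:
    def test_null_effect_independent_of_exposure(self, rng):
        n = 4000
        parts = pd.DataFrame({"participant_id": range(n), "community": "old_town"})
        expo = rng.uniform(0, 400, n)
        out = make_outcomes(parts, expo, OutcomeModel(beta_exposure=0.0,
                                                      covariate_effects={}), seed=3)
        hi = out.healthy[expo > np.median(expo)]
        lo = out.healthy[expo <= np.median(expo)]
        table = [[hi.sum(), (~hi).sum()], [lo.sum(), (~lo).sum()]]
        assert stats.chi2_contingency(table)[1] > 0.01

    def test_saturation_at_large_beta(self, rng):
        n = 500
        parts = pd.DataFrame({"participant_id": range(n), "community": "old_town"})
        expo = rng.uniform(0, 400, n)
        out = make_outcomes(parts, expo, OutcomeModel(beta_exposure=1e4, intercept=0.0,
                                                      covariate_effects={}), seed=4)
        thresh = expo.mean()
        agree = (out.healthy == (expo > thresh)).mean()
        assert agree > 0.98

    def test_score_consistent_with_binary(self, rng):
        parts = pd.DataFrame({"participant_id": range(200), "community": "new_town"})
        out = make_outcomes(parts, rng.uniform(0, 300, 200), OutcomeModel(), seed=5)
        assert (out.loc[out.healthy, "health_score"] <= 3).all()
        assert (out.loc[~out.healthy, "health_score"] >= 4).all()

    def test_both_classes_present_at_defaults(self, rng):
        parts = pd.DataFrame({"participant_id": range(300), "community": "new_town"})
        expo = rng.normal(100, 13, 300)
        out = make_outcomes(parts, expo, OutcomeModel(), seed=6)
        assert 0.0 < out.healthy.mean() < 1.0
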