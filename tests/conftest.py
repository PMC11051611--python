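"""Shared fixtures: small rasters and trajectories built in memory."""

from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pytest

from alanex.mobility import Trajectory, WeightSeries
from alanex.nightscape import NTLRaster
from alanex.solar import night_windows_for_range

HK_TZ = timezone(timedelta(hours=8))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def flat_raster():
    """Constant 20×20 raster, 10 m pixels, value 42."""
    return NTLRaster(np.full((20, 20), 42.0), origin_x=0.0, origin_y=200.0, pixel_size=10.0)


@pytest.fixture()
def ramp_raster():
    """3×3 raster with values 1..9, 10 m pixels (row-major)."""
    return NTLRaster(np.arange(1.0, 10.0).reshape(3, 3), origin_x=0.0, origin_y=30.0,
                     pixel_size=10.0)


@pytest.fixture()
def random_raster(rng):
    vals = rng.uniform(0.0, 500.0, size=(64, 64))
    return NTLRaster(vals, origin_x=0.0, origin_y=640.0, pixel_size=10.0)


@pytest.fixture()
def hk_windows():
    """Night windows spanning one synthetic survey week (Hong Kong anchor)."""
    return night_windows_for_range(date(2021, 6, 7), 7, 114.1, 22.3, 8.0)


def build_trajectory(positions, start=None, interval=60.0, participant_id="p1",
                     utc_offset=8.0):
    """Trajectory from a list of (x, y), one fix per ``interval`` seconds."""
    if start is None:
        start = datetime(2021, 6, 7, 12, 0, tzinfo=HK_TZ)
    t0 = start.timestamp()
    pos = np.asarray(positions, dtype=float)
    times = t0 + interval * np.arange(len(pos))
    return Trajectory(participant_id=participant_id, times=times,
                      x=pos[:, 0], y=pos[:, 1], utc_offset=utc_offset,
                      nominal_interval=interval)


def all_night_weights(n: int) -> WeightSeries:
    """Uniform weights summing to exactly 1, every fix flagged night."""
    w = np.full(n, 1.0 / (n - 1))
    w[-1] = 0.0
    s = w.sum()
    for _ in range(3):
        if s == 1.0 or not s > 0:
            break
        w = w / s
        s = w.sum()
    return WeightSeries(weights=w, night_flags=np.ones(n, dtype=bool))


def supersample_disc_mean(raster, cx, cy, radius, n_side=1200):
    """Deterministic grid supersampling oracle for the disc mean.

    Lays an n_side×n_side lattice over the disc's bounding square, keeps the
    points inside the disc and on the raster, drops nodata, and averages the
    pixel values under the half-open pixel convention.
    """
    xs = cx - radius + (2.0 * radius) * (np.arange(n_side) + 0.5) / n_side
    ys = cy - radius + (2.0 * radius) * (np.arange(n_side) + 0.5) / n_side
    X, Y = np.meshgrid(xs, ys)
    inside = (X - cx) ** 2 + (Y - cy) ** 2 <= radius**2
    X, Y = X[inside], Y[inside]
    p = raster.pixel_size
    cols = np.floor((X - raster.origin_x) / p).astype(int)
    rows = np.floor((raster.origin_y - Y) / p).astype(int)
    nr, nc = raster.shape
    ok = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
    rows, cols = rows[ok], cols[ok]
    good = ~raster.nodata_mask[rows, cols]
    return float(raster.values[rows[good], cols[good]].mean())
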