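"""GPS trajectories: assembly, night masking, and temporal weights.

A :class:`Trajectory` is an ordered series of timestamped planar positions at
a nominal one-minute spacing.  Raw fixes are sorted, de-duplicated, optionally
smoothed by a constant-velocity Kalman filter, and resampled onto a regular
grid.  The temporal weight of visited location i is the fraction of the total
trajectory duration D spent there under left-constant attribution,

    WT_i = (t_{i+1} − t_i) / D,   i = 1..n−1,   WT_n = 0,

so the weights sum to one exactly.  Nighttime is the open interval between
local sunset and the next sunrise; a fix exactly at either boundary counts as
daytime (a measure-zero convention fixed for bit-reproducibility).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np

from .errors import TrajectoryError
from .solar import NightWindow

__all__ = [
    "GPSFix",
    "Trajectory",
    "WeightSeries",
    "assemble_trajectory",
    "night_mask",
    "temporal_weights",
]


@dataclass(frozen=True)
class GPSFix:
    """One timestamped position; ``t`` must be timezone-aware."""

    t: datetime
    x: float
    y: float
    lon: float | None = None
    lat: float | None = None

    def __post_init__(self) -> None:
        if self.t.tzinfo is None:
            raise TrajectoryError("GPS fix timestamps must carry a UTC offset")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise TrajectoryError("GPS fix coordinates must be finite")


@dataclass
class Trajectory:
    """Regularized fix series for one participant.

    Positions are metres in the working planar CRS; times are stored as epoch
    seconds (UTC) with the original offset kept for serialization and solar
    computation.  ``gap_flags`` marks resampled fixes that fall inside a raw
    data gap longer than the assembly threshold.
    """

    participant_id: str
    times: np.ndarray  # epoch seconds, UTC
    x: np.ndarray
    y: np.ndarray
    utc_offset: float = 0.0  # hours
    nominal_interval: float = 60.0
    gap_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        n = self.times.size
        if n < 2 or self.x.size != n or self.y.size != n:
            raise TrajectoryError("trajectory needs >= 2 fixes with matching coordinate arrays")
        if not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("trajectory timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Total duration D = t_n − t_1 in seconds."""
        return float(self.times[-1] - self.times[0])

    @property
    def tzinfo(self) -> timezone:
        return timezone(timedelta(hours=self.utc_offset))

    @property
    def fixes(self) -> list[GPSFix]:
        tz = self.tzinfo
        return [
            GPSFix(t=datetime.fromtimestamp(t, tz), x=float(px), y=float(py))
            for t, px, py in zip(self.times, self.x, self.y)
        ]

    def datetimes(self) -> list[datetime]:
        tz = self.tzinfo
        return [datetime.fromtimestamp(t, tz) for t in self.times]


@dataclass
class WeightSeries:
    """Per-fix temporal weights and (optional) nighttime flags."""

    weights: np.ndarray
    night_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if (self.weights < 0).any():
            raise TrajectoryError("temporal weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise TrajectoryError("temporal weights must sum to 1")
        if self.night_flags is not None:
            self.night_flags = np.asarray(self.night_flags, dtype=bool)
            if self.night_flags.size != self.weights.size:
                raise TrajectoryError("night_flags and weights must be the same length")

    @property
    def night_fraction(self) -> float:
        if self.night_flags is None:
            raise TrajectoryError("night_flags not set")
        return float(self.weights[self.night_flags].sum())


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _kalman_smooth(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                   process_noise: float, measurement_noise: float) -> tuple[np.ndarray, np.ndarray]:
    """Constant-velocity Kalman filter per axis (white-acceleration model)."""
    out = []
    for z in (x, y):
        n = z.size
        state = np.array([z[0], 0.0])
        P = np.diag([measurement_noise**2, 25.0])
        r = measurement_noise**2
        est = np.empty(n)
        est[0] = z[0]
        for k in range(1, n):
            dt = t[k] - t[k - 1]
            F = np.array([[1.0, dt], [0.0, 1.0]])
            q = process_noise**2
            Q = q * np.array([[dt**4 / 4, dt**3 / 2], [dt**3 / 2, dt**2]])
            state = F @ state
            P = F @ P @ F.T + Q
            S = P[0, 0] + r
            K = P[:, 0] / S
            resid = z[k] - state[0]
            state = state + K * resid
            P = P - np.outer(K, P[0, :])
            est[k] = state[0]
        out.append(est)
    return out[0], out[1]


def assemble_trajectory(
    raw_fixes: Iterable[GPSFix],
    nominal_interval: float = 60.0,
    participant_id: str = "",
    smooth: bool = False,
    process_noise: float = 0.5,
    measurement_noise: float = 10.0,
    gap_threshold: float = 1800.0,
) -> Trajectory:
    """Sort, de-duplicate, optionally smooth, and resample raw fixes.

    Exact-duplicate timestamps collapse to their mean position.  When
    ``smooth`` is on, positions pass through a constant-velocity Kalman filter
    before linear resampling onto the regular ``nominal_interval`` grid
    anchored at the first timestamp.  Raw gaps longer than ``gap_threshold``
    seconds are flagged on the resampled fixes falling inside them, not
    filled with invented movement.
    """
    fixes = sorted(raw_fixes, key=lambda f: f.t)
    if len(fixes) < 2:
        raise TrajectoryError("need at least 2 raw fixes")
    utc_offset = fixes[0].t.utcoffset().total_seconds() / 3600.0
    t = np.array([f.t.timestamp() for f in fixes])
    x = np.array([f.x for f in fixes])
    y = np.array([f.y for f in fixes])
    # collapse exact-duplicate timestamps to the mean position
    uniq, inv, counts = np.unique(t, return_inverse=True, return_counts=True)
    if uniq.size != t.size:
        xs = np.bincount(inv, weights=x) / counts
        ys = np.bincount(inv, weights=y) / counts
        t, x, y = uniq, xs, ys
    if t.size < 2:
        raise TrajectoryError("fewer than 2 usable fixes after de-duplication")
    if smooth:
        x, y = _kalman_smooth(t, x, y, process_noise, measurement_noise)
    # resample onto the regular grid anchored at t[0]
    n_steps = int(np.floor((t[-1] - t[0]) / nominal_interval))
    grid = t[0] + nominal_interval * np.arange(n_steps + 1)
    gx = np.interp(grid, t, x)
    gy = np.interp(grid, t, y)
    gaps = np.diff(t) > gap_threshold
    gap_flags = np.zeros(grid.size, dtype=bool)
    for k in np.nonzero(gaps)[0]:
        gap_flags |= (grid > t[k]) & (grid < t[k + 1])
    return Trajectory(
        participant_id=participant_id,
        times=grid,
        x=gx,
        y=gy,
        utc_offset=utc_offset,
        nominal_interval=nominal_interval,
        gap_flags=gap_flags,
    )


# ---------------------------------------------------------------------------
# night masking and weights
# ---------------------------------------------------------------------------

def night_mask(traj: Trajectory, windows: Sequence[NightWindow]) -> np.ndarray:
    """Boolean per-fix nighttime flags from sunset/sunrise windows.

    A fix is night iff its timestamp lies strictly inside some window's
    (sunset, next-sunrise) interval; boundary hits count as daytime.  Polar
    ``always_night`` windows make their whole civil date night; the window set
    must cover every local date the trajectory spans (the day before the first
    fix included, so pre-dawn fixes resolve).
    """
    tz = traj.tzinfo
    dates = sorted({datetime.fromtimestamp(t, tz).date() for t in (traj.times[0], traj.times[-1])})
    first, last = dates[0], dates[-1]
    covered = {w.date for w in windows}
    need = {first + timedelta(days=-1)}
    d = first
    while d <= last:
        need.add(d)
        d += timedelta(days=1)
    missing = sorted(need - covered)
    if missing:
        raise TrajectoryError(f"night windows missing for dates: {missing}")
    mask = np.zeros(len(traj), dtype=bool)
    for w in windows:
        if w.polar_flag == "always_day":
            continue
        if w.polar_flag == "always_night":
            day_start = datetime(w.date.year, w.date.month, w.date.day, tzinfo=tz).timestamp()
            mask |= (traj.times >= day_start) & (traj.times < day_start + 86400.0)
            continue
        s = w.sunset.timestamp()
        r = w.sunrise_next.timestamp()
        mask |= (traj.times > s) & (traj.times < r)
    return mask


def temporal_weights(traj: Trajectory, windows: Sequence[NightWindow] | None = None) -> WeightSeries:
    """Left-constant temporal weights WT_i = (t_{i+1} − t_i)/D, last fix 0.

    When ``windows`` is given, per-fix night flags are attached so downstream
    exposure estimators can zero daytime terms.
    """
    dt = np.diff(traj.times)
    D = traj.duration
    if not D > 0:
        raise TrajectoryError("trajectory duration must be positive")
    w = np.append(dt / D, 0.0)
    # drive the floating sum to exactly 1 (downstream identities rely on it)
    s = w.sum()
    for _ in range(3):
        if s == 1.0 or not s > 0:
            break
        w = w / s
        s = w.sum()
    flags = night_mask(traj, windows) if windows is not None else None
    return WeightSeries(weights=w, night_flags=flags)
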