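"""Exposure estimators and the contextual-setting measurement matrix.

Four estimators of a participant's outdoor ALAN exposure are provided, the
cross of {residence-based (RBM), mobility-oriented (MOM)} approaches with
{in-situ, buffer-zone-average} methods:

* RBM in-situ:   the raster pixel containing the home location.
* RBM buffer:    the area-weighted mean of raster values over a disc of
                 radius r around home,  ∫ NTL da / ∫ da.
* MOM in-situ:   Σ_i NTL(x_i, y_i) · WT_i over the trajectory, where WT_i is
                 the temporal weight of fix i and daytime terms are zero.
* MOM buffer:    Σ_i WS_i · WT_i with WS_i the buffer mean around fix i.

The buffer integral is evaluated with exact closed-form disc–rectangle
intersection areas (machine precision, no supersampling).  Buffers straddling
the raster edge or nodata renormalize over the covered area.  Under the
default duration mode, D spans the whole trajectory and daytime momentary
exposures are assigned 0; a night-renormalized mode divides by the nighttime
weight instead (sensitivity analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ExposureError, RasterError
from .mobility import Trajectory, WeightSeries
from .nightscape import LinearCalibration, NTLRaster

__all__ = [
    "HomeLocation",
    "ExposureSetting",
    "ExposureResult",
    "pixel_at",
    "buffer_average",
    "disc_pixel_weights",
    "rbm_in_situ",
    "rbm_buffer",
    "mom_in_situ",
    "mom_buffer",
    "canonical_settings",
    "exposure_matrix",
]

DurationMode = Literal["full", "night"]


@dataclass(frozen=True)
class HomeLocation:
    """A participant's home in the working planar CRS (metres)."""

    x_h: float
    y_h: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_h) and np.isfinite(self.y_h)):
            raise ExposureError("home coordinates must be finite")


@dataclass(frozen=True)
class ExposureSetting:
    """One cell of the contextual-setting matrix.

    approach × method × raster resolution × buffer radius × cross-calibration.
    Buffer settings are only defined on the fine (10 m) product; in-situ
    settings carry no radius; cross-calibration applies to the coarse in-situ
    settings (130 m and 500 m) that have a calibration toward the reference
    sensor.
    """

    approach: Literal["MOM", "RBM"]
    method: Literal["in_situ", "buffer"]
    resolution: float
    radius: float | None = None
    cross_calibrated: bool = False

    def __post_init__(self) -> None:
        if self.method == "buffer":
            if self.radius is None:
                raise ExposureError("buffer settings require a radius")
            if self.resolution != 10:
                raise ExposureError("buffer-zone settings are defined on the fine 10 m product only")
            if self.cross_calibrated:
                raise ExposureError("cross-calibration applies to coarse in-situ settings only")
        else:
            if self.radius is not None:
                raise ExposureError("in-situ settings carry no radius")
            if self.cross_calibrated and self.resolution not in (130, 500):
                raise ExposureError("cross-calibration applies to the 130 m / 500 m settings")

    @property
    def label(self) -> str:
        """Canonical label, e.g. M_r500m_CC, R_b065m."""
        prefix = "M" if self.approach == "MOM" else "R"
        if self.method == "in_situ":
            body = f"r{int(self.resolution):03d}m"
        else:
            body = f"b{int(self.radius):03d}m"
        return f"{prefix}_{body}" + ("_CC" if self.cross_calibrated else "")

    @property
    def base_key(self) -> tuple:
        """Measurement key ignoring cross-calibration (raw value shared)."""
        return (self.approach, self.method, self.resolution, self.radius)


@dataclass(frozen=True)
class ExposureResult:
    """One participant's scalar exposure under one contextual setting."""

    participant_id: str
    setting_label: str
    value: float
    night_fraction: float | None = None


# ---------------------------------------------------------------------------
# point and buffer primitives
# ---------------------------------------------------------------------------

def pixel_at(raster: NTLRaster, x: float, y: float) -> float:
    """Value of the unique pixel whose half-open extent contains (x, y)."""
    try:
        row, col = raster.rowcol(x, y)
    except RasterError as exc:
        raise ExposureError(str(exc)) from exc
    v = raster.values[row, col]
    if raster.nodata_mask[row, col]:
        raise ExposureError(f"nodata pixel at ({x}, {y}) [row {row}, col {col}]")
    return float(v)


def _disc_quadrant_area(x: np.ndarray, y: np.ndarray, r: float) -> np.ndarray:
    """Area of {X²+Y²≤r², X≤x, Y≤y} for a disc of radius r centred at 0.

    Closed form from the antiderivative I(t) = ∫_{-r}^{t} sqrt(r²−s²) ds,
    split at the chord |t| = sqrt(r²−y²); exact up to floating rounding.
    """
    x = np.clip(np.asarray(x, dtype=np.float64), -r, r)
    y = np.asarray(y, dtype=np.float64)

    def I(t: np.ndarray) -> np.ndarray:
        t = np.clip(t, -r, r)
        return 0.5 * (t * np.sqrt(np.maximum(r * r - t * t, 0.0))
                      + r * r * (np.arcsin(t / r) + np.pi / 2.0))

    full = 2.0 * I(x)  # y ≥ r: no vertical cut
    c = np.sqrt(np.maximum(r * r - np.minimum(np.abs(y), r) ** 2, 0.0))
    a = np.clip(x, -c, c)
    mid = y * (a + c) + I(a) - I(-c)
    pos = y >= 0.0
    left = np.where(pos, 2.0 * I(np.minimum(x, -c)), 0.0)
    right = np.where(pos & (x > c), 2.0 * (I(x) - I(np.minimum(c, r))), 0.0)
    inner = mid + left + right
    out = np.where(y >= r, full, np.where(y <= -r, 0.0, inner))
    return out


def disc_pixel_weights(
    raster: NTLRaster, cx: float, cy: float, radius: float
) -> tuple[slice, slice, np.ndarray]:
    """Exact intersection areas of the disc with every in-raster pixel.

    Returns (row slice, col slice, area grid) covering the disc's bounding
    box clipped to the raster; areas for pixels outside the disc are 0.
    """
    p = raster.pixel_size
    nr, nc = raster.shape
    c0 = max(0, math.floor((cx - radius - raster.origin_x) / p))
    c1 = min(nc - 1, math.floor((cx + radius - raster.origin_x) / p))
    r0 = max(0, math.floor((raster.origin_y - (cy + radius)) / p))
    r1 = min(nr - 1, math.floor((raster.origin_y - (cy - radius)) / p))
    if c1 < c0 or r1 < r0:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    xs = raster.origin_x + p * np.arange(c0, c1 + 2) - cx          # corner x, ascending
    ys = raster.origin_y - p * np.arange(r0, r1 + 2) - cy          # corner y, descending
    X, Y = np.meshgrid(xs, ys)
    G = _disc_quadrant_area(X, Y, radius)
    # inclusion–exclusion over the 4 corners of each pixel
    area = G[:-1, 1:] - G[:-1, :-1] - G[1:, 1:] + G[1:, :-1]
    area = np.maximum(area, 0.0)  # clamp -0.0 / rounding dust
    return slice(r0, r1 + 1), slice(c0, c1 + 1), area


def _disc_mean(raster: NTLRaster, cx: float, cy: float, radius: float,
               kernel_cache: dict | None = None) -> float:
    """Exact disc mean; the area kernel depends only on the centre's sub-pixel
    offset, so with a cache repeated offsets reuse one exact kernel."""
    p = raster.pixel_size
    fx = (cx - raster.origin_x) / p
    fy = (raster.origin_y - cy) / p
    jf = math.floor(fx)
    if_ = math.floor(fy)
    u = fx - jf
    v = fy - if_
    ent = None
    if kernel_cache is not None:
        ent = kernel_cache.get((round(u, 9), round(v, 9)))
    if ent is None:
        rp = radius / p
        j0 = math.floor(fx - rp) - jf
        j1 = math.floor(fx + rp) - jf
        i0 = math.floor(fy - rp) - if_
        i1 = math.floor(fy + rp) - if_
        xs = p * (np.arange(j0, j1 + 2) - u)       # corner x offsets, ascending
        ys = p * (v - np.arange(i0, i1 + 2))       # corner y offsets, descending
        X, Y = np.meshgrid(xs, ys)
        G = _disc_quadrant_area(X, Y, radius)
        kern = np.maximum(G[:-1, 1:] - G[:-1, :-1] - G[1:, 1:] + G[1:, :-1], 0.0)
        ent = (i0, j0, kern)
        if kernel_cache is not None:
            kernel_cache[(round(u, 9), round(v, 9))] = ent
    i0, j0, kern = ent
    nr, nc = raster.shape
    ri0, cj0 = if_ + i0, jf + j0
    ka0, kb0 = max(0, -ri0), max(0, -cj0)
    ka1 = kern.shape[0] - max(0, ri0 + kern.shape[0] - nr)
    kb1 = kern.shape[1] - max(0, cj0 + kern.shape[1] - nc)
    if ka1 <= ka0 or kb1 <= kb0:
        raise ExposureError(f"buffer at ({cx}, {cy}) r={radius} lies entirely off the raster")
    w = kern[ka0:ka1, kb0:kb1]
    vals = raster.values[ri0 + ka0:ri0 + ka1, cj0 + kb0:cj0 + kb1]
    if raster.has_nodata:
        w = np.where(raster.nodata_mask[ri0 + ka0:ri0 + ka1, cj0 + kb0:cj0 + kb1], 0.0, w)
    denom = w.sum()
    if denom <= 0:
        raise ExposureError(f"buffer at ({cx}, {cy}) r={radius} covers no valid pixels")
    covered = vals[w > 0]
    if covered.size and np.ptp(covered) == 0.0:
        return float(covered[0])  # mean of identical values, exactly
    return float((vals * w).sum() / denom)


def buffer_average(raster: NTLRaster, cx: float, cy: float, radius: float) -> float:
    """Area-weighted mean of raster values over the disc of given radius.

    Σ value_k · a_k / Σ a_k with a_k the exact pixel–disc intersection area
    (closed-form disc–rectangle geometry, machine precision); nodata pixels
    and off-raster area are excluded from both numerator and denominator
    (edge buffers renormalize over covered area).
    """
    if not radius > 0:
        raise ExposureError("buffer radius must be positive")
    return _disc_mean(raster, cx, cy, radius)


class DiscSampler:
    """Repeated exact disc means over one raster at a fixed radius.

    Keeps two caches: evaluated positions (a participant dwelling at home
    revisits one position thousands of times) and sub-pixel area kernels
    (positions on any common lattice share a handful of offsets).  Results
    are bit-identical to :func:`buffer_average`.
    """

    def __init__(self, raster: NTLRaster, radius: float) -> None:
        if not radius > 0:
            raise ExposureError("buffer radius must be positive")
        self.raster = raster
        self.radius = radius
        self._kernels: dict = {}
        self._values: dict = {}

    def mean_at(self, x: float, y: float) -> float:
        key = (x, y)
        val = self._values.get(key)
        if val is None:
            val = _disc_mean(self.raster, x, y, self.radius, self._kernels)
            self._values[key] = val
        return val


# ---------------------------------------------------------------------------
# the four estimators
# ---------------------------------------------------------------------------

def rbm_in_situ(raster: NTLRaster, home: HomeLocation, participant_id: str = "",
                label: str = "") -> ExposureResult:
    """Residence-based in-situ exposure: the pixel at the home location."""
    return ExposureResult(participant_id, label or "R_in_situ",
                          pixel_at(raster, home.x_h, home.y_h))


def rbm_buffer(raster: NTLRaster, home: HomeLocation, radius: float,
               participant_id: str = "", label: str = "") -> ExposureResult:
    """Residence-based buffer exposure: disc mean around home."""
    return ExposureResult(participant_id, label or f"R_b{int(radius):03d}m",
                          buffer_average(raster, home.x_h, home.y_h, radius))


def _check_night_fixes(raster: NTLRaster, traj: Trajectory, night: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of night fixes; raises naming the first bad fix."""
    idx = np.nonzero(night)[0]
    p = raster.pixel_size
    cols = np.floor((traj.x[idx] - raster.origin_x) / p).astype(np.int64)
    rows = np.floor((raster.origin_y - traj.y[idx]) / p).astype(np.int64)
    nr, nc = raster.shape
    bad = (rows < 0) | (rows >= nr) | (cols < 0) | (cols >= nc)
    if bad.any():
        k = idx[np.nonzero(bad)[0][0]]
        raise ExposureError(f"night fix {k} at ({traj.x[k]}, {traj.y[k]}) outside raster extent")
    nod = raster.nodata_mask[rows, cols]
    if nod.any():
        k = idx[np.nonzero(nod)[0][0]]
        raise ExposureError(f"night fix {k} at ({traj.x[k]}, {traj.y[k]}) falls on nodata")
    return rows, cols


def _grouped_weight_sums(inv: np.ndarray, w: np.ndarray, n_groups: int) -> np.ndarray:
    """Per-group weight totals (single group: plain pairwise sum)."""
    if n_groups == 1:
        return np.array([w.sum()])
    return np.bincount(inv, weights=w)


def _mom_value(group_vals: np.ndarray, wsum: np.ndarray, weights: WeightSeries,
               mode: DurationMode) -> tuple[float, float]:
    """Combine per-group momentary values with grouped temporal weights.

    Works in ratio form so the algebraic identities hold bit-exactly in
    floating point: a stationary trajectory returns its single group value
    times the night share, and a constant surface returns the constant —
    degenerate-mobility and constant-surface identities are exact, not just
    close.  ``mode='full'`` multiplies by the nighttime share (daytime terms
    are zero but their duration still counts); ``mode='night'`` renormalizes
    over nighttime only.
    """
    s_night = float(wsum.sum()) if wsum.size > 1 else float(wsum[0])
    night = weights.night_flags
    s_day = float(weights.weights[~night].sum())
    s_total = s_night + s_day
    if s_night <= 0:
        raise ExposureError("trajectory has no nighttime weight")
    if np.ptp(group_vals) == 0.0:
        base = float(group_vals[0])  # weighted mean of identical values
    else:
        base = float(np.dot(group_vals, wsum)) / s_night
    nf = s_night / s_total
    if mode == "night":
        return base, nf
    return base * nf, nf


def mom_in_situ(raster: NTLRaster, traj: Trajectory, weights: WeightSeries,
                duration_mode: DurationMode = "full",
                participant_id: str = "", label: str = "") -> ExposureResult:
    """Mobility-oriented in-situ exposure: Σ NTL(x_i, y_i)·WT_i over night fixes.

    Daytime momentary exposures are assigned 0; their intervals still count in
    the duration D under the default mode.
    """
    if weights.night_flags is None:
        raise ExposureError("weights must carry night flags (pass windows to temporal_weights)")
    night = weights.night_flags
    rows, cols = _check_night_fixes(raster, traj, night)
    # group by pixel: a stationary trajectory reduces to one group, keeping
    # the degenerate-mobility identity MOM == RBM bit-exact
    flat = rows * raster.shape[1] + cols
    uniq, inv = np.unique(flat, return_inverse=True)
    wsum = _grouped_weight_sums(inv, weights.weights[night], uniq.size)
    vals = raster.values.ravel()[uniq]
    value, nf = _mom_value(vals, wsum, weights, duration_mode)
    return ExposureResult(participant_id, label or "M_in_situ", value, nf)


def mom_buffer(raster: NTLRaster, traj: Trajectory, radius: float, weights: WeightSeries,
               duration_mode: DurationMode = "full",
               participant_id: str = "", label: str = "",
               sampler: DiscSampler | None = None) -> ExposureResult:
    """Mobility-oriented buffer exposure: Σ WS_i·WT_i, WS_i the disc mean at fix i.

    Fixes are grouped by position first — a participant dwelling at home
    contributes one buffer evaluation weighted by the total time spent there —
    and evaluations go through a shared :class:`DiscSampler` when supplied
    (pass one per raster/radius to reuse kernels across participants).
    """
    if weights.night_flags is None:
        raise ExposureError("weights must carry night flags (pass windows to temporal_weights)")
    if sampler is None:
        sampler = DiscSampler(raster, radius)
    elif sampler.raster is not raster or sampler.radius != radius:
        raise ExposureError("sampler does not match the requested raster/radius")
    night = weights.night_flags
    idx = np.nonzero(night)[0]
    pts = np.stack([traj.x[idx], traj.y[idx]], axis=1)
    uniq, inv = np.unique(pts, axis=0, return_inverse=True)
    wsum = _grouped_weight_sums(inv, weights.weights[idx], uniq.shape[0])
    group_vals = np.empty(uniq.shape[0])
    for k, (px, py) in enumerate(uniq):
        try:
            group_vals[k] = sampler.mean_at(float(px), float(py))
        except ExposureError as exc:
            raise ExposureError(f"participant {participant_id or '?'}: night fix at "
                                f"({px}, {py}): {exc}") from exc
    value, nf = _mom_value(group_vals, wsum, weights, duration_mode)
    return ExposureResult(participant_id, label or f"M_b{int(radius):03d}m", value, nf)


# ---------------------------------------------------------------------------
# the contextual-setting matrix
# ---------------------------------------------------------------------------

IN_SITU_RESOLUTIONS = (500.0, 130.0, 10.0)
BUFFER_RADII = (65.0, 100.0, 250.0, 300.0, 500.0)


def canonical_settings() -> list[ExposureSetting]:
    """The 20 settings of the measurement design (×2 communities = 40 groups).

    {r500m, r500m_CC, r130m, r130m_CC, r010m, b065m, b100m, b250m, b300m,
    b500m} for each of the MOM and RBM approaches.
    """
    out: list[ExposureSetting] = []
    for approach in ("MOM", "RBM"):
        for res in IN_SITU_RESOLUTIONS:
            out.append(ExposureSetting(approach, "in_situ", res))
            if res in (500.0, 130.0):
                out.append(ExposureSetting(approach, "in_situ", res, cross_calibrated=True))
        for r in BUFFER_RADII:
            out.append(ExposureSetting(approach, "buffer", 10.0, radius=r))
    return out


def exposure_matrix(
    participants: pd.DataFrame,
    trajectories: Mapping[str, Trajectory],
    rasters: Mapping[tuple[str, float], NTLRaster],
    settings: Sequence[ExposureSetting] | None = None,
    calibrations: Mapping[float, LinearCalibration] | None = None,
    weights: Mapping[str, WeightSeries] | None = None,
    duration_mode: DurationMode = "full",
) -> pd.DataFrame:
    """Long-format exposure table: one row per participant × setting.

    ``participants`` needs columns participant_id, community, home_x, home_y;
    ``rasters`` maps (community, resolution) to the product for that setting;
    ``calibrations`` maps a coarse resolution to its LinearCalibration toward
    the reference sensor (required when a setting is cross-calibrated and
    applied to the final scalar, so CC = slope·raw + intercept);
    ``weights`` maps participant_id to a WeightSeries with night flags
    (required whenever a MOM setting is requested).
    """
    settings = list(settings) if settings is not None else canonical_settings()
    calibrations = calibrations or {}
    weights = weights or {}

    # resolve prerequisites up front (fail fast, naming the setting)
    communities = list(dict.fromkeys(participants["community"]))
    for s in settings:
        for com in communities:
            if (com, s.resolution) not in rasters:
                raise ExposureError(f"setting {s.label}: no raster for ({com}, {s.resolution} m)")
        if s.cross_calibrated and s.resolution not in calibrations:
            raise ExposureError(f"setting {s.label}: no cross-calibration for {s.resolution} m")

    base_keys = list(dict.fromkeys(s.base_key for s in settings))
    mom_needed = any(s.approach == "MOM" for s in settings)

    rows: list[dict] = []
    base_values: dict[tuple[str, tuple], tuple[float, float | None]] = {}
    # shared per-(community, radius) disc samplers for MOM trips
    samplers: dict[tuple[str, float], DiscSampler] = {}

    for rec in participants.itertuples(index=False):
        pid = str(rec.participant_id)
        com = rec.community
        home = HomeLocation(float(rec.home_x), float(rec.home_y))
        traj = trajectories.get(pid)
        wts = weights.get(pid)
        if mom_needed and (traj is None or wts is None):
            raise ExposureError(f"participant {pid}: MOM settings need a trajectory and weights")
        for key in base_keys:
            approach, method, res, radius = key
            raster = rasters[(com, res)]
            if approach == "RBM":
                if method == "in_situ":
                    val, nf = pixel_at(raster, home.x_h, home.y_h), None
                else:
                    val, nf = buffer_average(raster, home.x_h, home.y_h, radius), None
            else:
                if method == "in_situ":
                    r_ = mom_in_situ(raster, traj, wts, duration_mode, pid)
                else:
                    sampler = samplers.setdefault((com, radius), DiscSampler(raster, radius))
                    r_ = mom_buffer(raster, traj, radius, wts, duration_mode, pid,
                                    sampler=sampler)
                val, nf = r_.value, r_.night_fraction
            base_values[(pid, key)] = (val, nf)
        for s in settings:
            raw, nf = base_values[(pid, s.base_key)]
            val = raw
            if s.cross_calibrated:
                cal = calibrations[s.resolution]
                val = cal.slope * raw + cal.intercept
            rows.append(
                {
                    "participant_id": pid,
                    "community": com,
                    "setting": s.label,
                    "value": val,
                    "night_fraction": nf,
                }
            )
    return pd.DataFrame(rows)


def matrix_to_wide(matrix: pd.DataFrame) -> pd.DataFrame:
    """Wide pivot of the long exposure table (participants × settings)."""
    return matrix.pivot_table(index=["participant_id", "community"],
                              columns="setting", values="value").reset_index()
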