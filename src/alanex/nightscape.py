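"""Nighttime-light (NTL) rasters and radiometric / cross-sensor calibration.

An :class:`NTLRaster` is a single-band georeferenced grid of luminosity in a
planar metric CRS.  Satellite products arrive either pre-calibrated in band
radiance (nW·cm⁻²·sr⁻¹, the common exposure unit) or as raw digital numbers
(DN) that must pass through a sensor-specific radiometric calibration:

* power-law sensors (Luojia1-01 style):  L = DN^1.5 / 1e10  (W·m⁻²·sr⁻¹·μm⁻¹)
* gain/bias sensors (SDGSAT-1 style):    L = DN·Gain + Bias

Spectral radiance is converted to band radiance by a single configurable
scalar (default: bandwidth in μm × 1e5, i.e. W·m⁻² → nW·cm⁻² times the band
width).  Sensors with different spatial resolutions are made comparable by
area-mean resolution degradation, and different spectral responses by an
affine cross-calibration fitted on paired buffer-zone means.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError, RasterError

__all__ = [
    "NTLRaster",
    "SensorSpec",
    "LinearCalibration",
    "calibrate_power_law",
    "calibrate_gain_bias",
    "to_band_radiance",
    "degrade_resolution",
    "sample_buffer_pairs",
    "fit_cross_calibration",
    "apply_calibration",
]

UnitsTag = Literal["DN", "spectral_radiance", "band_radiance"]

#: default W·m⁻²·sr⁻¹·μm⁻¹ → nW·cm⁻²·sr⁻¹ scale (1 W·m⁻² = 1e5 nW·cm⁻²)
SPECTRAL_TO_BAND_SCALE = 1.0e5


@dataclass
class NTLRaster:
    """Single-band luminosity grid in a planar metric CRS.

    ``origin_x, origin_y`` locate the **upper-left corner** of the grid in
    metres; rows run southward.  Pixel extents are half-open: pixel (i, j)
    covers [x0, x0+p) × (y0−p, y0], so any point belongs to exactly one pixel.
    ``nodata`` marks invalid/cloud pixels and is propagated, never averaged.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    pixel_size: float
    crs_tag: str = "local-metric"
    nodata: float = -9999.0
    units_tag: str = "band_radiance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise RasterError("raster grid must be 2-D with at least one cell")
        if not self.pixel_size > 0:
            raise RasterError(f"pixel_size must be > 0, got {self.pixel_size}")
        bad = ~np.isfinite(self.values) & ~self.nodata_mask
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise RasterError(f"non-finite value at cell ({i}, {j})")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        nr, nc = self.shape
        return (
            self.origin_x,
            self.origin_y - nr * self.pixel_size,
            self.origin_x + nc * self.pixel_size,
            self.origin_y,
        )

    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean mask of invalid cells (cached; values are treated as immutable)."""
        cached = getattr(self, "_mask_cache", None)
        if cached is None:
            if np.isnan(self.nodata):
                cached = np.isnan(self.values)
            else:
                cached = self.values == self.nodata
            object.__setattr__(self, "_mask_cache", cached)
        return cached

    @property
    def has_nodata(self) -> bool:
        cached = getattr(self, "_has_nodata", None)
        if cached is None:
            cached = bool(self.nodata_mask.any())
            object.__setattr__(self, "_has_nodata", cached)
        return cached

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Index of the unique pixel whose half-open extent contains (x, y)."""
        p = self.pixel_size
        col = math.floor((x - self.origin_x) / p)
        row = math.floor((self.origin_y - y) / p)
        # closed top edge: y == origin_y belongs to row 0 (handled by floor(0)=0)
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise RasterError(f"point ({x}, {y}) outside raster extent {self.extent}")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return (xmin <= x < xmax) and (ymin < y <= ymax)

    def with_values(self, values: np.ndarray, units_tag: str | None = None) -> "NTLRaster":
        return replace(self, values=values, units_tag=units_tag or self.units_tag)

    def valid_mean(self) -> float:
        m = ~self.nodata_mask
        if not m.any():
            raise RasterError("raster has no valid cells")
        return float(self.values[m].mean())


@dataclass(frozen=True)
class SensorSpec:
    """Static configuration of an NTL sensor.

    ``calibration_kind`` selects the DN→radiance model and which coefficient
    fields are required: ``power_law`` needs ``power_exponent``/``power_scale``
    (defaults 1.5 and 1e10), ``gain_bias`` needs ``gain`` and ``bias``;
    ``precalibrated`` products carry band radiance already.
    """

    name: str
    nominal_resolution: float
    spectral_range: tuple[float, float] = (400.0, 900.0)
    bandwidth: float = 500.0  # nm
    calibration_kind: Literal["precalibrated", "power_law", "gain_bias"] = "precalibrated"
    gain: float | None = None
    bias: float | None = None
    power_exponent: float = 1.5
    power_scale: float = 1.0e10

    def __post_init__(self) -> None:
        if not self.bandwidth > 0:
            raise CalibrationError("bandwidth must be positive")
        if self.calibration_kind == "gain_bias" and (self.gain is None or self.bias is None):
            raise CalibrationError(f"sensor {self.name}: gain/bias calibration requires gain and bias")

    @property
    def band_conversion_factor(self) -> float:
        """Default spectral→band radiance factor: bandwidth(μm) × 1e5."""
        return (self.bandwidth / 1000.0) * SPECTRAL_TO_BAND_SCALE


@dataclass(frozen=True)
class LinearCalibration:
    """Affine map making a predictor sensor's radiance comparable to a reference.

    ``reference ≈ slope · predictor + intercept`` fitted by OLS on paired
    buffer-zone means; units are nW·cm⁻²·sr⁻¹ on both sides.
    """

    slope: float
    intercept: float
    r2: float
    n_samples: int
    reference_name: str = "reference"
    predictor_name: str = "predictor"
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise CalibrationError(f"R² out of [0,1]: {self.r2}")
        if self.n_samples < 3:
            raise CalibrationError("cross-calibration needs at least 3 samples")

    def to_json(self) -> str:
        return json.dumps(
            {
                "reference": self.reference_name,
                "predictor": self.predictor_name,
                "slope": self.slope,
                "intercept": self.intercept,
                "r2": self.r2,
                "n": self.n_samples,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearCalibration":
        d = json.loads(text)
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r2=d["r2"],
            n_samples=d["n"],
            reference_name=d.get("reference", "reference"),
            predictor_name=d.get("predictor", "predictor"),
        )


# ---------------------------------------------------------------------------
# radiometric calibration
# ---------------------------------------------------------------------------

def calibrate_power_law(dn_raster: NTLRaster, spec: SensorSpec) -> NTLRaster:
    """DN → spectral radiance through L = DN^exponent / scale.

    Negative DN are rejected (they have no physical radiance); nodata cells
    pass through untouched.
    """
    if dn_raster.units_tag != "DN":
        raise CalibrationError(f"expected units_tag 'DN', got {dn_raster.units_tag!r}")
    if spec.calibration_kind != "power_law":
        raise CalibrationError(f"sensor {spec.name} is not a power-law sensor")
    valid = ~dn_raster.nodata_mask
    neg = valid & (dn_raster.values < 0)
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise CalibrationError(f"negative DN at cell ({i}, {j})")
    out = dn_raster.values.copy()
    out[valid] = np.power(dn_raster.values[valid], spec.power_exponent) / spec.power_scale
    return dn_raster.with_values(out, units_tag="spectral_radiance")


def calibrate_gain_bias(dn_raster: NTLRaster, spec: SensorSpec) -> NTLRaster:
    """DN → spectral radiance through L = DN·Gain + Bias; nodata preserved."""
    if dn_raster.units_tag != "DN":
        raise CalibrationError(f"expected units_tag 'DN', got {dn_raster.units_tag!r}")
    if spec.calibration_kind != "gain_bias":
        raise CalibrationError(f"sensor {spec.name} is not a gain/bias sensor")
    valid = ~dn_raster.nodata_mask
    out = dn_raster.values.copy()
    out[valid] = dn_raster.values[valid] * spec.gain + spec.bias
    return dn_raster.with_values(out, units_tag="spectral_radiance")


def to_band_radiance(
    raster: NTLRaster, spec: SensorSpec, factor: float | None = None
) -> NTLRaster:
    """Spectral radiance (per μm) → band radiance in nW·cm⁻²·sr⁻¹.

    The conversion is one configurable scalar multiply; by default it is
    bandwidth(μm) × 1e5 (unit change W·m⁻² → nW·cm⁻² times the band width),
    so any alternative convention is a one-argument change.
    """
    if raster.units_tag != "spectral_radiance":
        raise CalibrationError(f"expected units_tag 'spectral_radiance', got {raster.units_tag!r}")
    f = spec.band_conversion_factor if factor is None else float(factor)
    if not f > 0:
        raise CalibrationError(f"band conversion factor must be positive, got {f}")
    valid = ~raster.nodata_mask
    out = raster.values.copy()
    out[valid] = raster.values[valid] * f
    return raster.with_values(out, units_tag="band_radiance")


# ---------------------------------------------------------------------------
# resolution degradation
# ---------------------------------------------------------------------------

def degrade_resolution(
    raster: NTLRaster, factor: int, pad: Literal["reject", "nodata"] = "reject"
) -> NTLRaster:
    """Coarsen by an integer factor with nodata-aware block means.

    Each output pixel is the area-weighted (here: equal-area, so arithmetic)
    mean of its factor×factor block, ignoring nodata cells in both numerator
    and denominator; an all-nodata block stays nodata.  ``pad='nodata'`` pads
    non-divisible grids with nodata on the bottom/right edge.
    """
    if not (isinstance(factor, (int, np.integer)) and factor >= 1):
        raise RasterError(f"degradation factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    vals = raster.values
    mask = raster.nodata_mask
    nr, nc = vals.shape
    if nr % factor or nc % factor:
        if pad == "reject":
            raise RasterError(
                f"grid {nr}×{nc} not divisible by factor {factor} (use pad='nodata')"
            )
        nr2 = math.ceil(nr / factor) * factor
        nc2 = math.ceil(nc / factor) * factor
        pv = np.full((nr2, nc2), raster.nodata, dtype=np.float64)
        pv[:nr, :nc] = vals
        pm = np.ones((nr2, nc2), dtype=bool)
        pm[:nr, :nc] = mask
        vals, mask, nr, nc = pv, pm, nr2, nc2
    blocks = vals.reshape(nr // factor, factor, nc // factor, factor)
    bmask = (~mask).reshape(nr // factor, factor, nc // factor, factor)
    counts = bmask.sum(axis=(1, 3))
    sums = np.where(bmask, blocks, 0.0).sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    out = np.where(counts > 0, means, raster.nodata)
    return replace(
        raster,
        values=out,
        pixel_size=raster.pixel_size * factor,
    )


# ---------------------------------------------------------------------------
# cross-sensor calibration
# ---------------------------------------------------------------------------

def sample_buffer_pairs(
    reference: NTLRaster,
    predictor: NTLRaster,
    n_points: int = 300,
    radius: float = 1000.0,
    seed: int | None = None,
    max_attempts_factor: int = 100,
    min_separation: float = 0.0,
) -> np.ndarray:
    """Paired buffer-zone means (reference, predictor) at random locations.

    Points are drawn uniformly (seeded) inside the spatial overlap of the two
    rasters; a point is rejected when its buffer is entirely nodata or
    off-raster on either product, or closer than ``min_separation`` to an
    already-accepted point.  ``min_separation = 2·radius`` yields
    non-overlapping buffer zones, which keeps the samples independent and the
    OLS standard errors of the fitted cross-calibration honest.  Returns an
    (n, 2) array.
    """
    from .exposure import buffer_average  # local import: avoids a cycle
    from .errors import ExposureError

    if n_points < 3:
        raise CalibrationError("need at least 3 sample points")
    if not radius > 0:
        raise CalibrationError("buffer radius must be positive")
    rx0, ry0, rx1, ry1 = reference.extent
    px0, py0, px1, py1 = predictor.extent
    xmin, xmax = max(rx0, px0), min(rx1, px1)
    ymin, ymax = max(ry0, py0), min(ry1, py1)
    if xmin >= xmax or ymin >= ymax:
        raise CalibrationError("rasters do not overlap spatially")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[float, float]] = []
    accepted: list[tuple[float, float]] = []
    attempts = 0
    cap = max_attempts_factor * n_points
    min_sep2 = min_separation**2
    while len(pairs) < n_points and attempts < cap:
        attempts += 1
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if min_sep2 > 0 and accepted:
            pts = np.asarray(accepted)
            if np.min((pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2) < min_sep2:
                continue
        try:
            a = buffer_average(reference, x, y, radius)
            b = buffer_average(predictor, x, y, radius)
        except (RasterError, ExposureError):
            continue  # buffer entirely nodata / off one raster
        pairs.append((a, b))
        accepted.append((x, y))
    if len(pairs) < n_points:
        raise CalibrationError(
            f"could only place {len(pairs)} of {n_points} valid buffers in {attempts} attempts"
        )
    return np.asarray(pairs)


def fit_cross_calibration(
    pairs: np.ndarray | Sequence[tuple[float, float]],
    reference_name: str = "reference",
    predictor_name: str = "predictor",
) -> LinearCalibration:
    """OLS of reference buffer means on predictor buffer means.

    Returns slope/intercept (with standard errors) and R² of the linear model
    reference = slope·predictor + intercept.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise CalibrationError("pairs must be an (n ≥ 3, 2) array of (reference, predictor)")
    ref, pred = arr[:, 0], arr[:, 1]
    if np.ptp(pred) == 0:
        raise CalibrationError("degenerate predictor: zero variance")
    res = stats.linregress(pred, ref)
    return LinearCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_samples=arr.shape[0],
        reference_name=reference_name,
        predictor_name=predictor_name,
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


def apply_calibration(raster_or_value, cal: LinearCalibration):
    """Apply the affine cross-calibration slope·x + intercept.

    Accepts a scalar, an array, or an :class:`NTLRaster` (nodata preserved).
    The pipeline default applies this to final per-setting exposure scalars;
    raster-level application is available for sensitivity checks.
    """
    if isinstance(raster_or_value, NTLRaster):
        valid = ~raster_or_value.nodata_mask
        out = raster_or_value.values.copy()
        out[valid] = out[valid] * cal.slope + cal.intercept
        return raster_or_value.with_values(out)
    x = np.asarray(raster_or_value, dtype=np.float64)
    out = x * cal.slope + cal.intercept
    if np.ndim(raster_or_value) == 0:
        return float(out)
    return out
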