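"""Synthetic nightscapes, multi-sensor views, trajectories, cohorts, outcomes.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without confidential GPS records or
licensed satellite imagery:

* two community archetypes — a bright *old town* of narrow street canyons
  around dark residential blocks (mean luminosity ≈ 325.32 nW·cm⁻²·sr⁻¹)
  and a dimmer *new town* of sparse bright patches in a dark matrix
  (≈ 210.78) — rendered as 10 m grids with multiplicative lognormal texture;
* three-sensor views of one truth nightscape: the fine product untouched and
  130 m / 500 m degradations with affine radiometric distortion plus pixel
  noise, parameterized so cross-calibrating back to the fine product should
  recover a known slope/intercept;
* home-anchored 7-day one-minute trajectories: a daytime wander plus
  Poisson-counted nighttime excursions away from home;
* cohorts with community-specific socio-demographic marginals, and binary
  health outcomes drawn from a logistic model with a known exposure effect.

Everything is a pure function of (parameters, seed).  The world lives on a
local planar grid; a configurable lon/lat anchor (default Hong Kong,
114.1°E 22.3°N, UTC+8) supplies solar geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import AlanexError
from .exposure import HomeLocation
from .mobility import Trajectory
from .nightscape import NTLRaster, degrade_resolution
from .solar import NightWindow

__all__ = [
    "CommunityArchetype",
    "TrajectoryProfile",
    "OutcomeModel",
    "OLD_TOWN",
    "NEW_TOWN",
    "CITYWIDE",
    "ANCHOR_LON",
    "ANCHOR_LAT",
    "ANCHOR_UTC_OFFSET",
    "DEFAULT_DEMOGRAPHICS",
    "make_nightscape",
    "make_multisensor",
    "MultisensorSet",
    "make_trajectory",
    "make_population",
    "make_outcomes",
]

# solar anchor of the synthetic world (Hong Kong)
ANCHOR_LON = 114.1
ANCHOR_LAT = 22.3
ANCHOR_UTC_OFFSET = 8.0


@dataclass(frozen=True)
class CommunityArchetype:
    """Structural parameters of one community nightscape.

    ``heterogeneity`` is the coefficient of variation of the multiplicative
    lognormal texture (street lighting is strongly right-skewed); the raster
    is rescaled so its mean hits ``target_mean`` exactly.
    """

    name: str
    target_mean: float
    street_spacing: float = 100.0  # m
    bright_level: float = 900.0
    dark_level: float = 60.0
    heterogeneity: float = 0.5
    patch_density: float = 12.0  # patches per km², new_town only
    patch_radius: float = 60.0  # m
    node_density: float = 0.0  # extra-bright commercial nodes per km² on lattice archetypes
    node_radius: float = 50.0  # m
    street_cv: float = 0.0  # CV of per-street brightness (arterials vs side lanes)
    largescale_cv: float = 0.0  # CV of the smooth district-scale brightness field
    largescale_length: float = 1000.0  # m, correlation length of that field

    def __post_init__(self) -> None:
        if not (self.bright_level > self.dark_level >= 0):
            raise AlanexError("need bright_level > dark_level >= 0")
        if not self.target_mean > 0:
            raise AlanexError("target_mean must be positive")


#: old town: bright street canyons enclosing residential blocks whose ambient
#: floor is lifted by street-light spillover — the whole district is bright and
#: the spillover also homogenizes it (lower texture CV than the new town)
#: sparse extra-bright commercial nodes (night markets, main-road junctions)
#: give nighttime destinations a brightness contrast of their own
OLD_TOWN = CommunityArchetype(name="old_town", target_mean=325.32,
                              street_spacing=80.0, bright_level=900.0, dark_level=120.0,
                              heterogeneity=0.25, node_density=6.0, node_radius=50.0)
#: new town: sparse bright patches on a much darker open matrix
NEW_TOWN = CommunityArchetype(name="new_town", target_mean=210.78,
                              street_spacing=250.0, bright_level=450.0, dark_level=30.0,
                              patch_density=25.0, patch_radius=70.0)
#: citywide nightscape for cross-sensor calibration sampling: street lattice
#: modulated by a district-scale brightness field so 1-km buffer means vary
#: length is far above the coarsest sensor footprint, so block-averaging does
#: not attenuate buffer-mean variance (which would bias slope recovery)
CITYWIDE = CommunityArchetype(name="citywide", target_mean=270.0,
                              street_spacing=100.0, bright_level=900.0, dark_level=50.0,
                              largescale_cv=0.4, largescale_length=8000.0)


def _lognormal_texture(rng: np.random.Generator, shape: tuple[int, int], cv: float) -> np.ndarray:
    """Unit-mean multiplicative lognormal texture with the given CV."""
    if cv <= 0:
        return np.ones(shape)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=shape)


def _largescale_field(rng: np.random.Generator, shape: tuple[int, int],
                      cv: float, length_px: float) -> np.ndarray | float:
    """Smooth unit-mean district-scale brightness field (bilinear lognormal)."""
    if cv <= 0:
        return 1.0
    from scipy.ndimage import zoom

    step = max(4, int(round(length_px)))
    gh = shape[0] // step + 2
    gw = shape[1] // step + 2
    sigma2 = math.log(1.0 + cv * cv)
    grid = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=(gh, gw))
    field = zoom(grid, step, order=1)
    return field[: shape[0], : shape[1]]


def make_nightscape(
    archetype: CommunityArchetype,
    width: int = 650,
    height: int = 650,
    pixel_size: float = 10.0,
    seed: int | None = None,
    origin_x: float = 0.0,
    origin_y: float | None = None,
    with_mask: bool = False,
):
    """Seeded community nightscape at 10 m; mean scaled to the target exactly.

    ``new_town`` renders sparse bright circular patches on a dark matrix; any
    other archetype renders a bright street lattice on dark blocks, optionally
    modulated by a smooth district-scale brightness field.  With
    ``with_mask=True`` also returns the residential mask (block interiors /
    patch surroundings) used for home placement — deliberately disjoint from
    the brightest pixels, which is what makes residence-based and
    mobility-oriented exposure differ.
    """
    if width < 32 or height < 32:
        raise AlanexError("nightscape needs dimensions >= 32x32")
    rng = np.random.default_rng(seed)
    base = np.full((height, width), archetype.dark_level, dtype=np.float64)
    street_px = max(2, int(round(20.0 / pixel_size)))  # ~20 m street canyons
    if archetype.name != "new_town":
        spacing_px = max(street_px + 2, int(round(archetype.street_spacing / pixel_size)))
        row_street = (np.arange(height) % spacing_px) < street_px
        col_street = (np.arange(width) % spacing_px) < street_px
        streets = row_street[:, None] | col_street[None, :]
        if archetype.street_cv > 0:
            # street lighting varies block by block (lamp types, signage,
            # shopfronts): one brightness factor per ~150 m street segment,
            # so the variation stays local rather than line-wide
            seg_px = max(2, int(round(150.0 / pixel_size)))
            s2 = math.log(1.0 + archetype.street_cv**2)
            sig = math.sqrt(s2)
            n_lines_r = height // spacing_px + 1
            n_lines_c = width // spacing_px + 1
            n_seg_w = width // seg_px + 1
            n_seg_h = height // seg_px + 1
            fr = rng.lognormal(-s2 / 2.0, sig, size=(n_lines_r, n_seg_w))
            fc = rng.lognormal(-s2 / 2.0, sig, size=(n_seg_h, n_lines_c))
            fr_px = fr[np.arange(height) // spacing_px][:, np.arange(width) // seg_px]
            fc_px = fc[np.arange(height) // seg_px][:, np.arange(width) // spacing_px]
            fr_px = np.where(row_street[:, None], fr_px, 0.0)
            fc_px = np.where(col_street[None, :], fc_px, 0.0)
            factor = np.maximum(fr_px, fc_px)
            base = np.where(streets, archetype.bright_level * factor, base)
        else:
            base[streets] = archetype.bright_level
        residential = ~streets
        if archetype.node_density > 0:
            area_km2 = width * height * pixel_size**2 / 1e6
            n_parents = max(1, rng.poisson(archetype.node_density * area_km2 / 1.8))
            ii, jj = np.indices(base.shape)
            node = np.zeros(base.shape, dtype=bool)
            node_near = np.zeros(base.shape, dtype=bool)
            nr_mean = archetype.node_radius / pixel_size
            for _ in range(n_parents):
                pi = rng.uniform(0, height)
                pj = rng.uniform(0, width)
                k = 1 + rng.poisson(0.8)  # lone junctions and market rows
                for _ in range(k):
                    ci = pi + rng.normal(0.0, 100.0 / pixel_size)
                    cj = pj + rng.normal(0.0, 100.0 / pixel_size)
                    nr_px = rng.uniform(0.4, 1.7) * nr_mean  # markets vary in size
                    excl_px = nr_px + 100.0 / pixel_size  # homes keep clear of the glare
                    d2 = (ii - ci) ** 2 + (jj - cj) ** 2
                    node |= d2 <= nr_px**2
                    node_near |= d2 <= excl_px**2
            base[node] = 2.0 * archetype.bright_level
            residential &= ~node_near
        # keep homes off the street edge
        interior = residential.copy()
        interior[:-1, :] &= residential[1:, :]
        interior[1:, :] &= residential[:-1, :]
        interior[:, :-1] &= residential[:, 1:]
        interior[:, 1:] &= residential[:, :-1]
        mask = interior
    else:
        area_km2 = width * height * pixel_size**2 / 1e6
        n_patches = max(3, rng.poisson(archetype.patch_density * area_km2))
        ii, jj = np.indices(base.shape)
        patch = np.zeros(base.shape, dtype=bool)
        near_inner = np.zeros(base.shape, dtype=bool)
        near = np.zeros(base.shape, dtype=bool)
        pr_mean = archetype.patch_radius / pixel_size
        for _ in range(n_patches):
            ci = rng.uniform(0, height)
            cj = rng.uniform(0, width)
            # venues vary in footprint, from corner shops to malls
            pr = rng.uniform(0.4, 1.7) * pr_mean
            core_b = rng.uniform(0.6, 1.4) * archetype.bright_level
            d2 = (ii - ci) ** 2 + (jj - cj) ** 2
            core = d2 <= pr**2
            base[core] = np.maximum(base[core], core_b)
            patch |= core
            near_inner |= d2 <= (2.0 * pr) ** 2
            near |= d2 <= (3.0 * pr) ** 2
        # homes sit in a perimeter band around the bright centres, at a
        # roughly uniform distance: close enough to be "patch surroundings",
        # far enough that the 65-m home buffer is not dominated by the patch
        mask = near & ~near_inner
        if not mask.any():
            mask = ~patch
    vals = base * _lognormal_texture(rng, base.shape, archetype.heterogeneity)
    vals *= _largescale_field(rng, base.shape, archetype.largescale_cv,
                              archetype.largescale_length / pixel_size)
    scale = archetype.target_mean / vals.mean()
    if not (0.05 < scale < 20.0):
        raise AlanexError(
            f"target mean {archetype.target_mean} unattainable from levels "
            f"({archetype.dark_level}, {archetype.bright_level})"
        )
    vals *= scale
    raster = NTLRaster(
        values=vals,
        origin_x=origin_x,
        origin_y=origin_y if origin_y is not None else height * pixel_size,
        pixel_size=pixel_size,
        crs_tag="local-metric",
        nodata=-9999.0,
        units_tag="band_radiance",
    )
    if with_mask:
        return raster, mask
    return raster


@dataclass(frozen=True)
class MultisensorSet:
    """Three sensor views of one truth nightscape plus the generating truth."""

    fine: NTLRaster  # 10 m, identical to truth
    mid: NTLRaster  # 130 m, distorted
    coarse: NTLRaster  # 500 m, distorted
    truth_params: dict = field(default_factory=dict)


def make_multisensor(
    truth: NTLRaster,
    distortions: Mapping[str, tuple[float, float, float]] | None = None,
    seed: int | None = None,
) -> MultisensorSet:
    """Fine/mid/coarse sensor views with known affine radiometric distortion.

    ``distortions`` maps level → (slope a, intercept b, noise_cv): the level
    is degraded (factors 13 and 50) and transformed y = x/a − b/a + ε with
    iid pixel noise of standard deviation noise_cv × sd(x/a), so regressing
    fine buffer means on distorted buffer means should recover slope ≈ a and
    intercept ≈ b.  Defaults echo realistic cross-sensor gains: mid
    (1.47, 23.14), coarse (2.20, 11.71); noise_cv defaults to 0.05, small
    enough that buffer-scale OLS recovery of (a, b) stays unbiased relative
    to its nominal standard errors (larger pixel noise induces
    errors-in-variables attenuation of the recovered slope).
    """
    distortions = dict(distortions or {})
    distortions.setdefault("mid", (1.47, 23.14, 0.05))
    distortions.setdefault("coarse", (2.20, 11.71, 0.05))
    rng = np.random.default_rng(seed)
    out: dict[str, NTLRaster] = {}
    for level, factor in (("mid", 13), ("coarse", 50)):
        a, b, noise_cv = distortions[level]
        deg = degrade_resolution(truth, factor, pad="nodata")
        valid = ~deg.nodata_mask
        x = deg.values[valid] / a - b / a
        sd = float(np.std(x))
        noise = rng.normal(0.0, noise_cv * sd, size=x.shape)
        vals = deg.values.copy()
        vals[valid] = x + noise
        out[level] = deg.with_values(vals)
    return MultisensorSet(
        fine=truth,
        mid=out["mid"],
        coarse=out["coarse"],
        truth_params={lvl: {"slope": d[0], "intercept": d[1], "noise_cv": d[2]}
                      for lvl, d in distortions.items()},
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryProfile:
    """Behavioural parameters of one synthetic participant's week.

    Nighttime is spent at home apart from Poisson-counted excursions of the
    given radius; daytime is a mean-reverting wander around home.  The survey
    week defaults to 7 consecutive days of one-minute fixes.
    """

    home: HomeLocation
    days: int = 7
    excursions_per_night: float = 2.0
    excursion_radius: float = 500.0
    excursion_duration: float = 60.0  # minutes
    max_favourite_spots: int = 3  # habitual nighttime destinations per person
    day_radius: float = 800.0
    step_interval: float = 60.0  # seconds
    start_date: Date = Date(2021, 6, 7)
    bounds: tuple[float, float, float, float] | None = None  # xmin, ymin, xmax, ymax

    def __post_init__(self) -> None:
        if self.excursions_per_night < 0 or self.excursion_radius < 0:
            raise AlanexError("excursion rate and radius must be nonnegative")
        if self.days < 1 or self.step_interval <= 0:
            raise AlanexError("need days >= 1 and a positive step interval")


def make_trajectory(
    profile: TrajectoryProfile,
    night_windows: Sequence[NightWindow],
    seed: int | None = None,
    utc_offset: float = ANCHOR_UTC_OFFSET,
    attraction=None,
    attraction_power: float = 1.5,
) -> Trajectory:
    """Seeded 1-minute trajectory over the survey week.

    Daytime positions follow a mean-reverting random walk around home with
    stationary spread ≈ ``day_radius``; nighttime positions sit at home
    except during excursions — out-bound walk, dwell, return.  Excursions
    target one of the participant's few habitual night spots (drawn once per
    person within ``excursion_radius``): people revisit the same lit street,
    park or centre rather than a fresh random point each night, so their
    aggregated nighttime exposure keeps a persistent personal signature.
    Positions are clipped to ``bounds``.
    """
    rng = np.random.default_rng(seed)
    hx, hy = profile.home.x_h, profile.home.y_h
    tz = timezone(timedelta(hours=utc_offset))
    t0 = datetime(profile.start_date.year, profile.start_date.month,
                  profile.start_date.day, tzinfo=tz).timestamp()
    n = profile.days * int(round(86400.0 / profile.step_interval))
    times = t0 + profile.step_interval * np.arange(n)

    night = np.zeros(n, dtype=bool)
    for w in night_windows:
        if w.polar_flag == "always_day":
            continue
        if w.polar_flag == "always_night":
            ds = datetime(w.date.year, w.date.month, w.date.day, tzinfo=tz).timestamp()
            night |= (times >= ds) & (times < ds + 86400.0)
            continue
        night |= (times > w.sunset.timestamp()) & (times < w.sunrise_next.timestamp())

    # daytime mean-reverting wander (discrete Ornstein–Uhlenbeck around home);
    # night fixes are pinned to home before excursions are painted on
    phi = 0.95
    sigma = profile.day_radius * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, sigma, size=(n, 2))
    dev = lfilter([1.0], [1.0, -phi], eps, axis=0)
    x = hx + dev[:, 0]
    y = hy + dev[:, 1]
    x[night] = hx
    y[night] = hy

    # habitual night spots, drawn once per participant; when an attraction
    # surface is given, candidate destinations are weighted by brightness —
    # nightlife gravitates to lit venues, not random field points
    n_spots = int(rng.integers(1, profile.max_favourite_spots + 1))
    n_cand = max(8, 4 * n_spots)
    cand_theta = rng.uniform(0.0, 2.0 * np.pi, size=n_cand)
    cand_dist = rng.uniform(0.3, 1.0, size=n_cand) * profile.excursion_radius
    cand = np.stack([cand_dist * np.cos(cand_theta), cand_dist * np.sin(cand_theta)], axis=1)
    if attraction is not None:
        bright = np.array([max(0.0, attraction(hx + dx, hy + dy)) for dx, dy in cand])
        w = (bright + 1.0) ** attraction_power
        pick = rng.choice(n_cand, size=n_spots, replace=False, p=w / w.sum())
    else:
        pick = np.arange(n_spots)
    spots = cand[pick]

    # nighttime excursions within each night window
    steps_per_min = 60.0 / profile.step_interval
    for w in night_windows:
        if w.polar_flag != "normal":
            continue
        s, r = w.sunset.timestamp(), w.sunrise_next.timestamp()
        in_win = np.nonzero((times > s) & (times < r))[0]
        if in_win.size < 10:
            continue
        for _ in range(rng.poisson(profile.excursions_per_night)):
            dur_steps = max(6, int(round(max(10.0, rng.normal(
                profile.excursion_duration, profile.excursion_duration / 4.0)) * steps_per_min)))
            dur_steps = min(dur_steps, in_win.size)
            start = int(rng.integers(0, in_win.size - dur_steps + 1))
            seg = in_win[start:start + dur_steps]
            dx, dy = spots[int(rng.integers(0, n_spots))]
            dx += rng.normal(0.0, 20.0)  # same haunt, not the same bench
            dy += rng.normal(0.0, 20.0)
            m = seg.size
            out_n = max(1, m // 3)
            back_n = max(1, m // 3)
            dwell_n = m - out_n - back_n
            frac = np.concatenate([
                np.linspace(0.0, 1.0, out_n, endpoint=False),
                np.ones(max(dwell_n, 0)),
                np.linspace(1.0, 0.0, back_n),
            ])[:m]
            jitter = rng.normal(0.0, 5.0, size=(m, 2))  # GPS-scale wobble while moving
            x[seg] = hx + frac * dx + jitter[:, 0] * (frac > 0)
            y[seg] = hy + frac * dy + jitter[:, 1] * (frac > 0)

    # positions at half-metre precision (GPS fixes are no finer); a common
    # lattice also lets exposure evaluation reuse sub-pixel disc kernels
    x = np.round(x * 2.0) / 2.0
    y = np.round(y * 2.0) / 2.0
    if profile.bounds is not None:
        xmin, ymin, xmax, ymax = profile.bounds
        np.clip(x, xmin, xmax, out=x)
        np.clip(y, ymin, ymax, out=y)
    return Trajectory(
        participant_id="",
        times=times,
        x=x,
        y=y,
        utc_offset=utc_offset,
        nominal_interval=profile.step_interval,
    )


# ---------------------------------------------------------------------------
# cohort and outcomes
# ---------------------------------------------------------------------------

#: default marginal proportions per community (old town / new town cohorts)
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, dict[str, float]]] = {
    "old_town": {
        "gender": {"male": 0.423, "female": 0.577},
        "age_group": {"18-24": 0.154, "25-44": 0.500, "45-64": 0.346},
        "income_group": {"low": 0.452, "middle": 0.308, "high": 0.240},
        "education_group": {"low": 0.356, "middle": 0.529, "high": 0.115},
        "marital_group": {"single": 0.510, "married": 0.385, "others": 0.105},
    },
    "new_town": {
        "gender": {"male": 0.462, "female": 0.538},
        "age_group": {"18-24": 0.202, "25-44": 0.490, "45-64": 0.308},
        "income_group": {"low": 0.260, "middle": 0.462, "high": 0.278},
        "education_group": {"low": 0.346, "middle": 0.538, "high": 0.116},
        "marital_group": {"single": 0.558, "married": 0.337, "others": 0.105},
    },
}


def _draw_categorical(rng: np.random.Generator, spec: Mapping[str, float], n: int) -> np.ndarray:
    cats = list(spec)
    probs = np.array([spec[c] for c in cats], dtype=float)
    if abs(probs.sum() - 1.0) > 0.005:
        raise AlanexError(f"category proportions must sum to 1, got {probs.sum():.4f} for {cats}")
    probs = probs / probs.sum()
    return rng.choice(cats, size=n, p=probs)


def make_population(
    n_per_community: int,
    demographics_spec: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
    seed: int | None = None,
    masks: Mapping[str, tuple[NTLRaster, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Cohort table with community-specific socio-demographic marginals.

    ``masks`` maps community → (raster, residential boolean mask); homes are
    placed uniformly over mask cells (uniform within the chosen cell).
    Without masks, home coordinates are left NaN for the caller to fill.
    """
    if n_per_community < 1:
        raise AlanexError("need at least one participant per community")
    spec = demographics_spec or DEFAULT_DEMOGRAPHICS
    rng = np.random.default_rng(seed)
    frames = []
    for com, axes in spec.items():
        d = {"participant_id": [f"{com}-{i:04d}" for i in range(n_per_community)],
             "community": com}
        df = pd.DataFrame(d)
        for axis, props in axes.items():
            df[axis] = _draw_categorical(rng, props, n_per_community)
        if masks and com in masks:
            raster, mask = masks[com]
            cells = np.argwhere(mask)
            if cells.size == 0:
                raise AlanexError(f"community {com}: empty residential mask")
            pick = cells[rng.integers(0, len(cells), size=n_per_community)]
            p = raster.pixel_size
            # uniform within the cell, snapped to the half-metre lattice but
            # kept strictly inside the chosen cell
            off_x = np.clip(np.round(rng.random(n_per_community) * p * 2.0) / 2.0, 0.5, p - 0.5)
            off_y = np.clip(np.round(rng.random(n_per_community) * p * 2.0) / 2.0, 0.5, p - 0.5)
            df["home_x"] = raster.origin_x + pick[:, 1] * p + off_x
            df["home_y"] = raster.origin_y - pick[:, 0] * p - off_y
        else:
            df["home_x"] = np.nan
            df["home_y"] = np.nan
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic ground truth for the binary health outcome.

    ``beta_exposure`` is the log-odds effect per ``exposure_scale`` radiance
    units; the intercept anchors the healthy share near the configured level
    when exposure is at its centring point.  With ``center_mode='community'``
    exposure enters as the deviation from its community mean — community-level
    brightness differences are treated as confounded baseline, and the causal
    signal is the within-community contrast, which is what the per-community
    health models estimate.  The default effect size is set so that, at a
    cohort of ~100 per community with within-community exposure spread of
    ~0.13 scaled units, the realized true-exposure Wald statistic is ≈ 4–5: strong
    enough to rank clearly, weak enough to keep outcome probabilities off the
    boundary.  Small covariate effects keep the adjustment meaningful.
    """

    beta_exposure: float = 30.0
    intercept: float = 2.3  # keeps the realized healthy share near the ~0.88 anchor
    exposure_scale: float = 100.0
    center: float | None = None
    center_mode: str = "community"  # or "overall"
    covariate_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "age_group": {"45-64": -0.6},
            "income_group": {"low": -0.3},
        }
    )


def make_outcomes(
    participants: pd.DataFrame,
    true_exposures: Sequence[float],
    model: OutcomeModel = OutcomeModel(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Bernoulli health outcomes from the logistic ground-truth model.

    healthy ~ Bernoulli(expit(intercept + β·exposure_scaled + covariates));
    the 6-point self-rated score is back-filled consistently with the binary
    draw (healthy → 1–3, unhealthy → 4–6).
    """
    rng = np.random.default_rng(seed)
    expo = np.asarray(true_exposures, dtype=np.float64)
    if not np.all(np.isfinite(expo)):
        raise AlanexError("true exposures must be finite")
    xs = expo / model.exposure_scale
    if model.center is not None:
        centred = xs - model.center / model.exposure_scale
    elif model.center_mode == "community" and "community" in participants.columns:
        com = participants["community"].to_numpy()
        centred = xs.copy()
        for c in pd.unique(com):
            sel = com == c
            centred[sel] = xs[sel] - xs[sel].mean()
    else:
        centred = xs - float(xs.mean())
    lp = model.intercept + model.beta_exposure * centred
    for axis, effects in model.covariate_effects.items():
        if axis in participants.columns:
            for cat, eff in effects.items():
                lp = lp + eff * (participants[axis].to_numpy() == cat)
    from scipy.special import expit

    prob = expit(lp)
    healthy = rng.random(len(prob)) < prob
    score = np.where(healthy, rng.integers(1, 4, size=len(prob)),
                     rng.integers(4, 7, size=len(prob)))
    out = participants.copy()
    out["healthy"] = healthy
    out["health_score"] = score
    out["true_probability"] = prob
    return out
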