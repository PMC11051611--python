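"""End-to-end orchestration: simulate → calibrate → expose → compare → model.

This module wires the stages together for the bundled synthetic study: two
community nightscapes viewed by three sensors, a cohort with home-anchored
week-long trajectories, the 40-group contextual-setting exposure matrix, the
disparity-test battery, and the adjusted logistic health battery.  The same
functions back the command-line interface and the example scripts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_data as synth
from .exposure import canonical_settings, exposure_matrix, matrix_to_wide, mom_buffer
from .fileio import RunConfig, write_raster, write_trajectories
from .inference import run_comparison_battery, run_health_battery
from .mobility import Trajectory, WeightSeries, temporal_weights
from .nightscape import LinearCalibration, NTLRaster, fit_cross_calibration, sample_buffer_pairs
from .solar import NightWindow, night_windows_for_range
from .synthetic_data import (
    CITYWIDE,
    NEW_TOWN,
    OLD_TOWN,
    ANCHOR_LAT,
    ANCHOR_LON,
    ANCHOR_UTC_OFFSET,
    OutcomeModel,
    TrajectoryProfile,
    make_multisensor,
    make_nightscape,
    make_outcomes,
    make_population,
    make_trajectory,
)

__all__ = ["SimulatedStudy", "simulate_study", "run_pipeline"]

#: true-exposure setting used for outcome generation (fine-scale mobility)
TRUE_EXPOSURE_LABEL = "M_b065m"


@dataclass
class SimulatedStudy:
    """Everything one seeded synthetic study run produces upstream of stats."""

    participants: pd.DataFrame
    trajectories: dict[str, Trajectory]
    weights: dict[str, WeightSeries]
    rasters: dict[tuple[str, float], NTLRaster]
    calibrations: dict[float, LinearCalibration]
    night_windows: list[NightWindow]
    true_exposure: pd.Series | None = None
    meta: dict = field(default_factory=dict)


def simulate_study(
    seed: int = 0,
    n_per_community: int = 104,
    days: int = 7,
    grid_size: int = 650,
    pixel_size: float = 10.0,
    start_date: Date = Date(2021, 6, 7),
    excursions_per_night: float = 2.0,
    excursion_radius: float = 500.0,
    n_calibration_points: int = 300,
    calibration_radius: float = 1000.0,
    calibration_grid_size: int = 4550,
) -> SimulatedStudy:
    """Generate the full synthetic two-community study, deterministically.

    Nightscapes for the old-town and new-town archetypes are rendered at
    ``pixel_size`` (10 m) and viewed through three sensors (10/130/500 m with
    known affine distortion on the coarse products).  Cross-calibrations are
    fitted on a separate citywide nightscape large enough to hold
    ``n_calibration_points`` non-overlapping 1-km buffer zones — mirroring a
    citywide sampling campaign whose sample size is capped by how many
    disjoint buffers fit, and keeping the OLS standard errors honest.  Each
    of the ``2 × n_per_community`` participants receives a home inside their
    community's residential mask plus a week-long one-minute trajectory.
    Everything derives from ``seed`` alone.
    """
    root = np.random.default_rng(seed)
    windows = night_windows_for_range(start_date, days, ANCHOR_LON, ANCHOR_LAT, ANCHOR_UTC_OFFSET)

    rasters: dict[tuple[str, float], NTLRaster] = {}
    masks: dict[str, tuple[NTLRaster, np.ndarray]] = {}
    multisets = {}
    for arch in (OLD_TOWN, NEW_TOWN):
        rseed = int(root.integers(0, 2**31 - 1))
        truth, mask = make_nightscape(arch, grid_size, grid_size, pixel_size,
                                      seed=rseed, with_mask=True)
        ms = make_multisensor(truth, seed=int(root.integers(0, 2**31 - 1)))
        multisets[arch.name] = ms
        rasters[(arch.name, 10.0)] = ms.fine
        rasters[(arch.name, 130.0)] = ms.mid
        rasters[(arch.name, 500.0)] = ms.coarse
        masks[arch.name] = (truth, mask)

    # cross-calibration: reference = fine product, predictors = mid/coarse,
    # fitted on non-overlapping buffer pairs over a citywide nightscape
    city = make_nightscape(CITYWIDE, calibration_grid_size, calibration_grid_size,
                           pixel_size, seed=int(root.integers(0, 2**31 - 1)))
    city_ms = make_multisensor(city, seed=int(root.integers(0, 2**31 - 1)))
    calibrations: dict[float, LinearCalibration] = {}
    for res, pred in ((130.0, city_ms.mid), (500.0, city_ms.coarse)):
        pairs = sample_buffer_pairs(
            city_ms.fine, pred, n_points=n_calibration_points,
            radius=calibration_radius, seed=int(root.integers(0, 2**31 - 1)),
            min_separation=2.0 * calibration_radius,
        )
        calibrations[res] = fit_cross_calibration(
            pairs, reference_name="fine_10m",
            predictor_name=f"{'mid' if res == 130.0 else 'coarse'}_{int(res)}m",
        )
    del city, city_ms

    participants = make_population(
        n_per_community, seed=int(root.integers(0, 2**31 - 1)), masks=masks
    )

    trajectories: dict[str, Trajectory] = {}
    weights: dict[str, WeightSeries] = {}
    for rec in participants.itertuples(index=False):
        raster = rasters[(rec.community, 10.0)]
        xmin, ymin, xmax, ymax = raster.extent
        margin = 1.0
        # nightlife propensity varies strongly across people (many stay in,
        # a few are out most evenings); Gamma-distributed nightly rates make
        # nighttime mobility a first-order source of exposure differences
        rate = float(root.gamma(1.2, excursions_per_night / 1.2))
        profile = TrajectoryProfile(
            home=synth.HomeLocation(rec.home_x, rec.home_y),
            days=days,
            excursions_per_night=rate,
            excursion_radius=excursion_radius,
            start_date=start_date,
            bounds=(xmin + margin, ymin + margin, xmax - margin, ymax - margin),
        )
        traj = make_trajectory(profile, windows, seed=int(root.integers(0, 2**31 - 1)))
        traj.participant_id = str(rec.participant_id)
        trajectories[traj.participant_id] = traj
        weights[traj.participant_id] = temporal_weights(traj, windows)

    return SimulatedStudy(
        participants=participants,
        trajectories=trajectories,
        weights=weights,
        rasters=rasters,
        calibrations=calibrations,
        night_windows=windows,
        meta={
            "seed": seed,
            "n_per_community": n_per_community,
            "days": days,
            "grid_size": grid_size,
            "pixel_size": pixel_size,
            "distortions": {k: ms.truth_params for k, ms in multisets.items()},
        },
    )


def true_fine_scale_exposure(study: SimulatedStudy, radius: float = 65.0) -> pd.Series:
    """Ground-truth exposure: mobility-oriented 65-m buffer mean on the fine raster.

    This is the quantity health outcomes are generated from, so recovering it
    is the benchmark for every other contextual setting.
    """
    from .exposure import DiscSampler

    samplers: dict = {}
    com_by_pid = study.participants.set_index("participant_id")["community"]
    vals = {}
    for pid, traj in study.trajectories.items():
        com = com_by_pid.loc[pid]
        raster = study.rasters[(com, 10.0)]
        sampler = samplers.setdefault(com, DiscSampler(raster, radius))
        res = mom_buffer(raster, traj, radius, study.weights[pid],
                         participant_id=pid, sampler=sampler)
        vals[pid] = res.value
    s = pd.Series(vals, name="true_exposure")
    return s.loc[[str(p) for p in study.participants["participant_id"]]]


def run_pipeline(config: RunConfig, log=print) -> dict[str, Path]:
    """Full end-to-end run under one config; writes all result tables.

    Returns the mapping of artifact name → written path.  Outputs embed the
    config hash and seed so identical configurations reproduce byte-identical
    tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log(f"[alanex] config hash {config.config_hash}, seed {config.seed}")

    study = simulate_study(
        seed=config.seed,
        n_per_community=config.n_per_community,
        days=config.days,
        grid_size=config.grid_size,
        pixel_size=config.pixel_size,
        n_calibration_points=config.n_calibration_points,
        calibration_radius=config.calibration_radius,
    )
    paths: dict[str, Path] = {}
    for (com, res), raster in study.rasters.items():
        paths[f"raster_{com}_{int(res)}m"] = write_raster(raster, out / f"{com}_{int(res)}m.asc")
    paths["trajectories"] = write_trajectories(study.trajectories, out / "trajectories.csv")
    study.participants.to_csv(out / "cohort.csv", index=False)
    paths["cohort"] = out / "cohort.csv"
    for res, cal in study.calibrations.items():
        p = out / f"calibration_{int(res)}m.json"
        p.write_text(cal.to_json())
        paths[f"calibration_{int(res)}m"] = p
    log(f"[alanex] calibrations: " + ", ".join(
        f"{int(r)}m slope={c.slope:.3f} intercept={c.intercept:.2f} R2={c.r2:.3f}"
        for r, c in study.calibrations.items()))

    matrix = exposure_matrix(
        study.participants, study.trajectories, study.rasters,
        canonical_settings(), study.calibrations, study.weights,
        duration_mode=config.duration_mode,
    )
    matrix["config_hash"] = config.config_hash
    matrix.to_csv(out / "exposure_matrix.csv", index=False)
    matrix_to_wide(matrix).to_csv(out / "exposure_matrix_wide.csv", index=False)
    paths["exposure_matrix"] = out / "exposure_matrix.csv"
    log(f"[alanex] exposure matrix: {matrix.shape[0]} rows "
        f"({matrix['setting'].nunique()} settings x {matrix['participant_id'].nunique()} participants)")

    comparisons = run_comparison_battery(matrix.drop(columns=["config_hash"]))
    comparisons["config_hash"] = config.config_hash
    comparisons.to_csv(out / "comparisons.csv", index=False)
    paths["comparisons"] = out / "comparisons.csv"

    true_expo = true_fine_scale_exposure(study)
    health = make_outcomes(study.participants, true_expo.to_numpy(),
                           OutcomeModel(), seed=config.seed + 1)
    health.to_csv(out / "health_records.csv", index=False)
    paths["health_records"] = out / "health_records.csv"
    battery = run_health_battery(matrix.drop(columns=["config_hash"]), health,
                                 exposure_scale=config.exposure_scale,
                                 covariates=config.covariates)
    battery["config_hash"] = config.config_hash
    battery.to_csv(out / "health_models.csv", index=False)
    paths["health_models"] = out / "health_models.csv"

    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "settings": sorted(matrix["setting"].unique().tolist()),
        "meta": {k: v for k, v in study.meta.items() if k != "distortions"},
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = out / "manifest.json"
    log(f"[alanex] wrote {len(paths)} artifacts to {out}")
    return paths
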