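"""File I/O and run configuration.

Rasters are exchanged as single-band ESRI ASCII grids (a plain-text format
with NCOLS/NROWS/XLLCORNER/YLLCORNER/CELLSIZE/NODATA_VALUE header), with an
optional JSON sidecar (``<path>.meta.json``) carrying the CRS and units tags
the grid format cannot hold.  Trajectories and cohorts travel as CSV with
ISO-8601 timestamps that carry explicit UTC offsets.  Long-format CSV is the
canonical interchange between pipeline stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, RasterError, TrajectoryError
from .mobility import Trajectory
from .nightscape import NTLRaster

__all__ = [
    "read_raster",
    "write_raster",
    "read_trajectories",
    "write_trajectories",
    "read_cohort",
    "RunConfig",
]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_raster(raster: NTLRaster, path: str | Path) -> Path:
    """Write an ESRI ASCII grid plus a JSON sidecar for CRS/units tags."""
    path = Path(path)
    nr, nc = raster.shape
    yll = raster.origin_y - nr * raster.pixel_size
    with open(path, "w") as fh:
        fh.write(f"NCOLS {nc}\nNROWS {nr}\n")
        fh.write(f"XLLCORNER {raster.origin_x!r}\nYLLCORNER {yll!r}\n")
        fh.write(f"CELLSIZE {raster.pixel_size!r}\nNODATA_VALUE {raster.nodata!r}\n")
        np.savetxt(fh, raster.values, fmt="%.10g")
    sidecar = {"crs_tag": raster.crs_tag, "units_tag": raster.units_tag}
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar))
    return path


def read_raster(path: str | Path) -> NTLRaster:
    """Read an ESRI ASCII grid; round-trips values, geometry and nodata."""
    path = Path(path)
    if not path.exists():
        raise RasterError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        missing = [k for k in _HEADER_KEYS[:5] if k not in header]
        if missing:
            raise RasterError(f"{path}: malformed ESRI ASCII header, missing {missing}")
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nr, nc):
        raise RasterError(f"{path}: grid shape {values.shape} does not match header ({nr}, {nc})")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return NTLRaster(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nr * header["cellsize"],
        pixel_size=header["cellsize"],
        crs_tag=meta.get("crs_tag", "unspecified"),
        nodata=header.get("nodata_value", -9999.0),
        units_tag=meta.get("units_tag", "band_radiance"),
    )


# ---------------------------------------------------------------------------
# trajectories and cohorts
# ---------------------------------------------------------------------------

def write_trajectories(trajectories: Mapping[str, Trajectory], path: str | Path) -> Path:
    """CSV writer mirroring the reader: participant_id, timestamp, x, y."""
    frames = []
    for pid, traj in trajectories.items():
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "timestamp": [t.isoformat() for t in traj.datetimes()],
                    "x": traj.x,
                    "y": traj.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def read_trajectories(path: str | Path) -> dict[str, Trajectory]:
    """Read per-participant fix series from CSV; rows re-sorted per participant.

    Requires columns participant_id, timestamp (ISO-8601 with offset), x, y.
    Unparseable rows are rejected naming the first offending line.
    """
    df = pd.read_csv(path)
    needed = {"participant_id", "timestamp", "x", "y"}
    missing = needed - set(df.columns)
    if missing:
        raise TrajectoryError(f"{path}: missing columns {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    if ts.isna().any():
        row = int(np.nonzero(ts.isna().to_numpy())[0][0])
        raise TrajectoryError(f"{path}: unparseable timestamp at data row {row + 1}: "
                              f"{df['timestamp'].iloc[row]!r}")
    # recover the (assumed common) local offset from the first stamp
    first = datetime.fromisoformat(str(df["timestamp"].iloc[0]))
    if first.utcoffset() is None:
        raise TrajectoryError(f"{path}: timestamps must carry an explicit UTC offset")
    offset_h = first.utcoffset().total_seconds() / 3600.0
    epoch = ts.astype("int64").to_numpy() / 1e9
    out: dict[str, Trajectory] = {}
    for pid, sub in df.assign(_epoch=epoch).groupby("participant_id", sort=False):
        sub = sub.sort_values("_epoch")
        out[str(pid)] = Trajectory(
            participant_id=str(pid),
            times=sub["_epoch"].to_numpy(),
            x=sub["x"].to_numpy(dtype=float),
            y=sub["y"].to_numpy(dtype=float),
            utc_offset=offset_h,
        )
    return out


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Participant table: ids, community, home coordinates, demographics."""
    df = pd.read_csv(path)
    needed = {"participant_id", "community", "home_x", "home_y"}
    missing = needed - set(df.columns)
    if missing:
        raise TrajectoryError(f"{path}: missing columns {sorted(missing)}")
    dup = df["participant_id"].duplicated()
    if dup.any():
        raise TrajectoryError(
            f"{path}: duplicate participant ids: {sorted(df.loc[dup, 'participant_id'].unique())}")
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-backed).

    Every referenced path must resolve before execution (fail fast); the
    config hash is embedded in all outputs for reproducibility.
    """

    out_dir: str = "alanex_out"
    seed: int = 0
    n_per_community: int = 104
    days: int = 7
    grid_size: int = 650
    pixel_size: float = 10.0
    duration_mode: str = "full"
    cc_on_rasters: bool = False
    solar_mode: str = "community_anchor"
    exposure_scale: float = 100.0
    covariates: list[str] = field(default_factory=lambda: [
        "age_group", "gender", "income_group", "education_group", "marital_group"])
    n_calibration_points: int = 300
    calibration_radius: float = 1000.0
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "raw"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.raw = data
        if cfg.duration_mode not in ("full", "night"):
            raise ConfigError(f"duration_mode must be 'full' or 'night', got {cfg.duration_mode!r}")
        return cfg

    @property
    def config_hash(self) -> str:
        """Hash of the scientific settings (paths excluded: moving the output
        directory must not change what the pipeline computes)."""
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k not in ("raw", "out_dir")},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
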