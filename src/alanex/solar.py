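"""Sunset/sunrise computation (NOAA solar position algorithm).

Implements the NOAA General Solar Position Calculations used by the NOAA
sunrise/sunset calculator: Julian-century ephemeris of the sun's apparent
longitude and declination, the equation of time, and the hour angle at the
standard sunrise/sunset zenith of 90.833 deg (sun-centre altitude −0.833 deg,
which folds in atmospheric refraction and the solar semidiameter).  Accuracy
is a couple of seconds against the NOAA spreadsheet, far inside the ±2 min
contract that matters for assigning one-minute GPS fixes to day or night.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, timedelta, timezone
from typing import Literal

from .errors import TrajectoryError

__all__ = ["NightWindow", "sun_times", "solar_events", "night_windows_for_range"]

_ZENITH = 90.833  # degrees


@dataclass(frozen=True)
class NightWindow:
    """The nighttime interval anchored on one calendar date.

    ``sunset`` is the sunset of ``date`` and ``sunrise_next`` the sunrise of
    the following day; fixes strictly between the two are nighttime.  Polar
    conditions are reported through ``polar_flag`` instead of timestamps.
    """

    date: Date
    sunset: datetime | None
    sunrise_next: datetime | None
    polar_flag: Literal["normal", "always_day", "always_night"] = "normal"

    def __post_init__(self) -> None:
        if self.polar_flag == "normal" and not (self.sunset < self.sunrise_next):
            raise TrajectoryError(f"night window for {self.date}: sunset must precede next sunrise")


def _solar_quantities(jd: float) -> tuple[float, float]:
    """(equation of time [min], solar declination [rad]) at Julian day ``jd``."""
    jc = (jd - 2451545.0) / 36525.0
    g_l = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    g_a = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    ctr = (
        math.sin(math.radians(g_a)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(math.radians(2 * g_a)) * (0.019993 - 0.000101 * jc)
        + math.sin(math.radians(3 * g_a)) * 0.000289
    )
    true_long = g_l + ctr
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    declin = math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    eot = 4.0 * math.degrees(
        var_y * math.sin(2.0 * math.radians(g_l))
        - 2.0 * ecc * math.sin(math.radians(g_a))
        + 4.0 * ecc * var_y * math.sin(math.radians(g_a)) * math.cos(2.0 * math.radians(g_l))
        - 0.5 * var_y**2 * math.sin(4.0 * math.radians(g_l))
        - 1.25 * ecc**2 * math.sin(2.0 * math.radians(g_a))
    )
    return eot, declin


def sun_times(
    date: Date, lon: float, lat: float, utc_offset: float
) -> tuple[datetime | None, datetime | None, str]:
    """(sunrise, sunset, polar_flag) for one civil date at (lon, lat).

    ``utc_offset`` is the local offset in hours (e.g. 8 for Hong Kong);
    returned datetimes are timezone-aware in that offset.  Under polar day or
    night both timestamps are None and the flag says which.
    """
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        raise TrajectoryError(f"invalid coordinates lon={lon}, lat={lat}")
    # Julian day at local noon of the civil date
    jd = date.toordinal() + 1721424.5 + 0.5 - utc_offset / 24.0
    eot, declin = _solar_quantities(jd)
    lat_r = math.radians(lat)
    cos_ha = (
        math.cos(math.radians(_ZENITH)) / (math.cos(lat_r) * math.cos(declin))
        - math.tan(lat_r) * math.tan(declin)
    )
    if cos_ha > 1.0:
        return None, None, "always_night"
    if cos_ha < -1.0:
        return None, None, "always_day"
    ha = math.degrees(math.acos(cos_ha))
    tz = timezone(timedelta(hours=utc_offset))
    noon_min = 720.0 - 4.0 * lon - eot + utc_offset * 60.0  # minutes past local midnight
    day_start = datetime(date.year, date.month, date.day, tzinfo=tz)
    sunrise = day_start + timedelta(minutes=noon_min - 4.0 * ha)
    sunset = day_start + timedelta(minutes=noon_min + 4.0 * ha)
    return sunrise, sunset, "normal"


def solar_events(date: Date, lon: float, lat: float, utc_offset: float) -> NightWindow:
    """Night window anchored on ``date``: its sunset to the next day's sunrise."""
    _, sunset, flag = sun_times(date, lon, lat, utc_offset)
    sunrise_next, _, flag_next = sun_times(date + timedelta(days=1), lon, lat, utc_offset)
    if flag != "normal" or flag_next != "normal":
        # a polar condition on either side makes the whole window polar
        polar = flag if flag != "normal" else flag_next
        return NightWindow(date=date, sunset=None, sunrise_next=None, polar_flag=polar)
    return NightWindow(date=date, sunset=sunset, sunrise_next=sunrise_next)


def night_windows_for_range(
    start: Date, n_days: int, lon: float, lat: float, utc_offset: float
) -> list[NightWindow]:
    """Night windows for ``n_days`` consecutive dates beginning at ``start``.

    One extra leading window is included so fixes in the small hours of the
    first date (before that day's sunrise) are classified correctly.
    """
    return [
        solar_events(start + timedelta(days=k), lon, lat, utc_offset)
        for k in range(-1, n_days + 1)
    ]
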