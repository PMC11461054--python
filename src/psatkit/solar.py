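"""Solar elevation for day/night classification.

Implements the standard low-precision solar position algorithm (fractional
Julian century, geometric mean longitude/anomaly, equation of time, hour
angle -> elevation) as used by NOAA's solar calculator. Accuracy is a few
hundredths of a degree — far finer than needed to split archival samples
into day and night, where position uncertainty of the interpolated track
dominates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["solar_elevation", "is_day"]


def _julian_day(times: pd.DatetimeIndex) -> np.ndarray:
    # days since Unix epoch -> Julian day
    return times.asi8 / 86400e9 + 2440587.5


def solar_elevation(
    times: pd.DatetimeIndex, lon: np.ndarray, lat: np.ndarray
) -> np.ndarray:
    """Solar elevation angle (degrees) at each (time, lon, lat).

    ``times`` must be UTC (naive timestamps are taken as UTC). ``lon``/``lat``
    broadcast against ``times``.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    times = pd.DatetimeIndex(times)
    if times.tz is not None:
        times = times.tz_convert("UTC").tz_localize(None)
    jd = _julian_day(times)
    t = (jd - 2451545.0) / 36525.0  # Julian centuries since J2000

    # geometric mean longitude / anomaly of the sun (deg)
    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    mr = np.radians(m)
    # equation of centre and true longitude
    c = (
        np.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * mr) * (0.019993 - 0.000101 * t)
        + np.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.radians(omega))

    # obliquity (corrected) and declination
    e0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = e0 + 0.00256 * np.cos(np.radians(omega))
    decl = np.degrees(np.arcsin(np.sin(np.radians(eps)) * np.sin(np.radians(app_long))))

    # equation of time (minutes)
    y = np.tan(np.radians(eps / 2.0)) ** 2
    l0r = np.radians(l0)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2.0 * ecc * np.sin(mr)
        + 4.0 * ecc * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * ecc * ecc * np.sin(2 * mr)
    )

    minutes_utc = (
        times.hour * 60.0 + times.minute + times.second / 60.0
        + times.microsecond / 6e7
    )
    tst = np.mod(minutes_utc + eot + 4.0 * lon, 1440.0)  # true solar time, min
    ha = tst / 4.0 - 180.0  # hour angle, deg
    latr, declr, har = np.radians(lat), np.radians(decl), np.radians(ha)
    cos_zen = np.sin(latr) * np.sin(declr) + np.cos(latr) * np.cos(declr) * np.cos(har)
    return 90.0 - np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))


def is_day(times: pd.DatetimeIndex, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """True where the sun is above the horizon (elevation > 0 deg)."""
    return solar_elevation(times, lon, lat) > 0.0
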