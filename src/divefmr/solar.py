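"""Solar position from the NOAA Solar Calculator equations.

Implements the standard NOAA/Spencer approximation for solar declination and
the equation of time, good to a few tenths of a degree in elevation — ample
for day/night classification of dive records. Times are UTC.
"""

from __future__ import annotations

import numpy as np

__all__ = ["solar_elevation", "is_daytime"]

_SECONDS_PER_DAY = 86400.0


def _to_utc_components(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(day-of-year incl. fraction, fractional hour of day) from datetime64."""
    t = np.asarray(times, dtype="datetime64[s]")
    years = t.astype("datetime64[Y]")
    day_of_year = (t - years).astype("timedelta64[s]").astype(float) / _SECONDS_PER_DAY
    days = t.astype("datetime64[D]")
    frac_hour = (t - days).astype("timedelta64[s]").astype(float) / 3600.0
    return day_of_year, frac_hour


def solar_elevation(times: np.ndarray, lat: float, lon: float) -> np.ndarray:
    """Solar elevation angle (degrees) for UTC times at (lat, lon in degrees).

    Follows the NOAA General Solar Position Calculations: fractional year ->
    equation of time and declination (Spencer series) -> true solar time ->
    hour angle -> elevation via the spherical astronomy identity.
    """
    doy, hour = _to_utc_components(np.atleast_1d(np.asarray(times)))
    # fractional year (radians); 365.25 keeps leap years near-correct
    gamma = 2.0 * np.pi * (doy + (hour - 12.0) / 24.0) / 365.25
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    time_offset = eqtime + 4.0 * lon  # minutes; lon positive east
    tst = hour * 60.0 + time_offset  # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle
    lat_r = np.deg2rad(lat)
    cos_zenith = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    elevation = 90.0 - np.rad2deg(np.arccos(np.clip(cos_zenith, -1.0, 1.0)))
    return elevation


def is_daytime(
    times: np.ndarray, lat: float, lon: float, threshold_deg: float = 0.0
) -> np.ndarray:
    """Boolean day mask: solar elevation above ``threshold_deg`` (default 0°)."""
    return solar_elevation(times, lat, lon) > threshold_deg
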