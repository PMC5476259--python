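"""Photoperiod (sunrise-to-sunset hours) from standard solar geometry.

Day length is used as a seasonal covariate: every record receives the day
length for its sighting date computed at a single reference coordinate,
the geographical centre of the UK (Dunsop Bridge, Lancashire,
53.9419°N 2.5369°W). Across the survey window day length varies by only
about ten minutes between the centre of the UK and its extremes, so a
single reference point is adequate.

The computation follows the NOAA solar position equations: Julian-century
ephemeris for the solar declination, and the sunrise hour angle evaluated
at a solar altitude of -0.833° (accounting for atmospheric refraction and
the solar half-disc). Day length in hours is ``2·H/15`` with ``H`` the
sunrise hour angle in degrees at local solar noon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta
from math import acos, asin, cos, degrees, radians, sin, tan
from typing import Iterable

from murmuration.records import MurmurationRecord

__all__ = [
    "DayLengthContext",
    "UnsupportedLatitudeError",
    "solar_day_length",
    "attach_day_length",
    "UK_CENTRE_LAT",
    "UK_CENTRE_LON",
]

#: Geographical centre of the UK (Dunsop Bridge, Lancashire).
UK_CENTRE_LAT = 53.9419
UK_CENTRE_LON = -2.5369

#: Solar altitude at sunrise/sunset: 0.833° below the horizon covers
#: atmospheric refraction (~0.567°) plus the solar semi-diameter (~0.267°).
SUNRISE_ALTITUDE_DEG = -0.833

#: No polar day/night handling: the model is undefined poleward of ~66.5°.
MAX_SUPPORTED_LATITUDE = 66.5


class UnsupportedLatitudeError(ValueError):
    """Raised for polar-circle latitudes where the sun may not rise or set."""


@dataclass(frozen=True)
class DayLengthContext:
    """Reference coordinate and season origin used to date records.

    ``season_start`` is the calendar date mapped to ``day_index`` 1
    (1 October of the survey year); leap years are handled by ordinary
    calendar arithmetic.
    """

    ref_latitude: float = UK_CENTRE_LAT
    ref_longitude: float = UK_CENTRE_LON
    season_start: date = date(2014, 10, 1)

    def date_of(self, day_index: int) -> date:
        return self.season_start + timedelta(days=day_index - 1)


def _julian_day(when: date, hour_utc: float) -> float:
    # proleptic-Gregorian ordinal -> Julian Day; 1 Jan 2000 12:00 UTC = 2451545.0
    return when.toordinal() + 1721424.5 + hour_utc / 24.0


def _solar_declination_deg(jd: float) -> float:
    """Apparent solar declination (degrees) from the NOAA ephemeris."""
    t = (jd - 2451545.0) / 36525.0  # Julian centuries since J2000.0
    geom_mean_long = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    geom_mean_anom = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    m = radians(geom_mean_anom)
    eq_of_centre = (
        sin(m) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + sin(2 * m) * (0.019993 - 0.000101 * t)
        + sin(3 * m) * 0.000289
    )
    true_long = geom_mean_long + eq_of_centre
    omega = radians(125.04 - 1934.136 * t)
    apparent_long = true_long - 0.00569 - 0.00478 * sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - 0.001813 * t))) / 60.0) / 60.0
    obliq_corr = mean_obliq + 0.00256 * cos(omega)
    return degrees(asin(sin(radians(obliq_corr)) * sin(radians(apparent_long))))


def solar_day_length(when: date, latitude: float, longitude: float) -> float:
    """Sunrise-to-sunset duration in hours for *when* at a coordinate.

    The declination is evaluated at local solar noon (approximated as
    ``12h - longitude/15`` UTC); day length follows from the sunrise hour
    angle at the -0.833° altitude convention. The result is continuous in
    the date and lies strictly between 0 and 24 h for supported latitudes.

    Raises
    ------
    UnsupportedLatitudeError
        For latitudes poleward of ±66.5°, where polar day or night can
        make the hour angle undefined.
    """
    if abs(latitude) >= MAX_SUPPORTED_LATITUDE:
        raise UnsupportedLatitudeError(
            f"latitude {latitude} is poleward of ±{MAX_SUPPORTED_LATITUDE}°; "
            "polar day/night is not modelled"
        )
    solar_noon_utc = 12.0 - longitude / 15.0
    decl = radians(_solar_declination_deg(_julian_day(when, solar_noon_utc)))
    lat = radians(latitude)
    zenith = radians(90.0 - SUNRISE_ALTITUDE_DEG)
    cos_ha = cos(zenith) / (cos(lat) * cos(decl)) - tan(lat) * tan(decl)
    # |cos_ha| <= 1 is guaranteed within the supported latitude band
    ha_deg = degrees(acos(cos_ha))
    return 2.0 * ha_deg / 15.0


def attach_day_length(
    records: Iterable[MurmurationRecord],
    context: DayLengthContext | None = None,
) -> list[MurmurationRecord]:
    """Attach ``day_length_h`` to each record at the reference coordinate.

    Day length is specific only to the date of the sighting, never to its
    location: records sharing a ``day_index`` receive identical values.
    Returns new record instances; inputs are not mutated.
    """
    context = context or DayLengthContext()
    cache: dict[int, float] = {}
    out = []
    for rec in records:
        if rec.day_index not in cache:
            cache[rec.day_index] = solar_day_length(
                context.date_of(rec.day_index), context.ref_latitude, context.ref_longitude
            )
        out.append(replace(rec, day_length_h=cache[rec.day_index]))
    return out
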