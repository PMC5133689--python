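"""Time-zone assignment, UTC-to-local conversion, and solar day/night phases.

Breadcrumb timestamps arrive in UTC; understanding *when* someone drives
(rush hour, after dark) needs local clock time and the position of the sun.
This module resolves an IANA zone for a coordinate (fast bounding-box path
with a point-in-polygon fallback), converts instants with the system tz
database, and computes sunrise/sunset and civil twilight with the NOAA
solar-position equations (accuracy about +/-1 minute for |lat| < 60).

A trip's light phase is decided from its *start* instant and location:
``dawn`` between civil dawn and sunrise, ``day`` between sunrise and sunset,
``dusk`` between sunset and civil dusk, ``night`` otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta, timezone
from importlib.resources import files
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import shapely
from shapely.geometry import shape

__all__ = [
    "SolarDay",
    "TimeZoneMap",
    "assign_time_zone",
    "to_local",
    "from_local",
    "solar_day",
    "solar_elevation",
    "classify_trip_light",
    "PHASES",
]

PHASES = ("day", "night", "dawn", "dusk")

#: Solar elevation of the sun's upper limb at sunrise/sunset: geometric
#: horizon corrected for refraction (34') and the solar disc radius (16').
SUNRISE_ELEVATION = -0.833
CIVIL_ELEVATION = -6.0


# ----------------------------------------------------------------------
# Time zones
# ----------------------------------------------------------------------

class TimeZoneMap:
    """Point -> IANA zone lookup over a set of zone polygons.

    Points inside ``fast_bbox`` short-circuit to ``fast_zone`` without any
    geometry test; everything else is resolved by point-in-polygon. The
    packaged default polygon set is a deliberately simplified, synthetic
    four-zone CONUS partition (see ``data/tz_conus_synthetic.geojson``);
    pass your own GeoJSON for survey-accurate boundaries.
    """

    def __init__(
        self,
        zones: list[tuple[str, shapely.Geometry]],
        fast_bbox: tuple[float, float, float, float] | None = None,
        fast_zone: str | None = None,
    ):
        if not zones:
            raise ValueError("at least one zone polygon required")
        self.zones = zones
        self.fast_bbox = fast_bbox
        self.fast_zone = fast_zone
        for _, geom in zones:
            shapely.prepare(geom)

    @classmethod
    def from_geojson(
        cls,
        path: str | Path | None = None,
        fast_bbox: tuple[float, float, float, float] | None = None,
        fast_zone: str | None = None,
    ) -> "TimeZoneMap":
        """Load zones from a GeoJSON FeatureCollection with a ``tzid`` property."""
        if path is None or path == "":
            raw = files("drivecrumb.data").joinpath("tz_conus_synthetic.geojson").read_text()
        else:
            raw = Path(path).read_text()
        gj = json.loads(raw)
        zones = [(f["properties"]["tzid"], shape(f["geometry"])) for f in gj["features"]]
        return cls(zones, fast_bbox=fast_bbox, fast_zone=fast_zone)

    def lookup(self, lat: float, lon: float) -> str | None:
        """Zone id for one point, or None when no polygon contains it."""
        if self.fast_bbox is not None and self.fast_zone is not None:
            la0, la1, lo0, lo1 = self.fast_bbox
            if la0 <= lat <= la1 and lo0 <= lon <= lo1:
                return self.fast_zone
        pt = shapely.points(lon, lat)
        for tzid, geom in self.zones:
            if shapely.intersects(geom, pt):
                return tzid
        return None

    def lookup_many(self, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
        """Vectorised lookup; unresolved points get the empty string."""
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        out = np.full(lats.shape, "", dtype=object)
        todo = np.ones(lats.shape, dtype=bool)
        if self.fast_bbox is not None and self.fast_zone is not None:
            la0, la1, lo0, lo1 = self.fast_bbox
            fast = (lats >= la0) & (lats <= la1) & (lons >= lo0) & (lons <= lo1)
            out[fast] = self.fast_zone
            todo &= ~fast
        if todo.any():
            idx = np.flatnonzero(todo)
            for tzid, geom in self.zones:
                if not len(idx):
                    break
                hit = shapely.contains_xy(geom, lons[idx], lats[idx])
                out[idx[hit]] = tzid
                idx = idx[~hit]
        return out


def assign_time_zone(
    lat: float,
    lon: float,
    fast_bbox: tuple[float, float, float, float] | None = None,
    tz_map: TimeZoneMap | None = None,
    fast_zone: str = "America/Chicago",
) -> str | None:
    """Resolve the IANA zone for a point; None for unresolvable (offshore) points."""
    if tz_map is None:
        tz_map = TimeZoneMap.from_geojson(fast_bbox=fast_bbox, fast_zone=fast_zone)
    elif fast_bbox is not None:
        la0, la1, lo0, lo1 = fast_bbox
        if la0 <= lat <= la1 and lo0 <= lon <= lo1:
            return fast_zone
    return tz_map.lookup(lat, lon)


def to_local(timestamp_utc: datetime, tz_id: str) -> datetime:
    """Convert a UTC instant to zoned local time (same instant, new wall clock)."""
    if timestamp_utc.tzinfo is None:
        timestamp_utc = timestamp_utc.replace(tzinfo=timezone.utc)
    return timestamp_utc.astimezone(ZoneInfo(tz_id))


def from_local(timestamp_local: datetime, tz_id: str) -> tuple[datetime, bool]:
    """Convert naive local wall time to UTC.

    Returns ``(utc_instant, ok)``; ``ok`` is False for wall times that do
    not exist (spring-forward gap) or occur twice (fall-back), in which case
    the earlier/shifted mapping is returned but flagged rather than trusted.
    """
    tz = ZoneInfo(tz_id)
    aware = timestamp_local.replace(tzinfo=tz)
    utc = aware.astimezone(timezone.utc)
    # round-trip detects nonexistent times; fold detects ambiguous ones
    ok = utc.astimezone(tz).replace(tzinfo=None) == timestamp_local
    if aware.utcoffset() != timestamp_local.replace(tzinfo=tz, fold=1).utcoffset():
        ok = False
    return utc, ok


# ----------------------------------------------------------------------
# Solar position (NOAA spreadsheet equations)
# ----------------------------------------------------------------------

def _solar_params(jd: float) -> tuple[float, float]:
    """Solar declination (degrees) and equation of time (minutes) at Julian day jd."""
    jc = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = math.radians(m)
    c = (
        math.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mr) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(omega)
    epsr = math.radians(eps)
    decl = math.degrees(math.asin(math.sin(epsr) * math.sin(math.radians(app_long))))
    y = math.tan(epsr / 2.0) ** 2
    l0r = math.radians(l0)
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2.0 * ecc * math.sin(mr)
        + 4.0 * ecc * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mr)
    )
    return decl, eqtime


def _julian_day(d: date) -> float:
    """Julian day number at 00:00 UT."""
    y, m, dd = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + dd + b - 1524.5


def _hour_angle(lat: float, decl: float, elevation: float) -> float | None:
    """Half day-length hour angle (degrees) for the sun at `elevation`; None if no crossing."""
    latr, declr = math.radians(lat), math.radians(decl)
    cos_ha = (
        math.cos(math.radians(90.0 - elevation)) / (math.cos(latr) * math.cos(declr))
        - math.tan(latr) * math.tan(declr)
    )
    if cos_ha < -1.0 or cos_ha > 1.0:
        return None
    return math.degrees(math.acos(cos_ha))


def _event_utc(d: date, lat: float, lon: float, elevation: float, rising: bool) -> datetime | None:
    """UTC instant on local date d when the sun crosses `elevation` (rising/setting)."""
    jd0 = _julian_day(d)
    # iterate: evaluate declination/eqtime at progressively better estimates
    minutes = 720.0 - 4.0 * lon
    for _ in range(3):
        decl, eqtime = _solar_params(jd0 + minutes / 1440.0)
        ha = _hour_angle(lat, decl, elevation)
        if ha is None:
            return None
        noon = 720.0 - 4.0 * lon - eqtime
        minutes = noon - 4.0 * ha if rising else noon + 4.0 * ha
    return datetime(d.year, d.month, d.day, tzinfo=timezone.utc) + timedelta(minutes=minutes)


@dataclass
class SolarDay:
    """Sun events for one local calendar date at one location.

    Event fields are timezone-aware instants (local zone) or ``None`` in
    polar day/night cases where the crossing does not occur.
    """

    date_local: date
    sunrise: datetime | None
    sunset: datetime | None
    civil_dawn: datetime | None
    civil_dusk: datetime | None

    @property
    def daylength(self) -> timedelta | None:
        if self.sunrise is None or self.sunset is None:
            return None
        return self.sunset - self.sunrise


def solar_day(lat: float, lon: float, date_local: date, tz_id: str = "UTC") -> SolarDay:
    """Sunrise/sunset (-0.833 deg) and civil dawn/dusk (-6 deg) for a local date.

    Events are searched on the UTC date offset so that each returned instant
    falls on ``date_local`` in ``tz_id`` wherever that instant exists.
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError("latitude out of range")
    tz = ZoneInfo(tz_id)

    def find(elev: float, rising: bool) -> datetime | None:
        # try the UTC dates straddling the local date, keep the one landing on it
        for delta in (0, 1, -1):
            d = date_local + timedelta(days=delta)
            ev = _event_utc(d, lat, lon, elev, rising)
            if ev is not None and ev.astimezone(tz).date() == date_local:
                return ev.astimezone(tz)
        return None

    return SolarDay(
        date_local=date_local,
        sunrise=find(SUNRISE_ELEVATION, True),
        sunset=find(SUNRISE_ELEVATION, False),
        civil_dawn=find(CIVIL_ELEVATION, True),
        civil_dusk=find(CIVIL_ELEVATION, False),
    )


def solar_elevation(lat: float, lon: float, instant_utc: datetime) -> float:
    """Sun elevation in degrees (no refraction) at a UTC instant."""
    if instant_utc.tzinfo is not None:
        instant_utc = instant_utc.astimezone(timezone.utc)
    d = instant_utc.date()
    minutes = instant_utc.hour * 60.0 + instant_utc.minute + instant_utc.second / 60.0
    decl, eqtime = _solar_params(_julian_day(d) + minutes / 1440.0)
    tst = (minutes + eqtime + 4.0 * lon) % 1440.0
    ha = math.radians(tst / 4.0 - 180.0)
    latr, declr = math.radians(lat), math.radians(decl)
    sin_el = math.sin(latr) * math.sin(declr) + math.cos(latr) * math.cos(declr) * math.cos(ha)
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_el))))


def classify_trip_light(
    start_local: datetime,
    lat: float,
    lon: float,
    night_definition: str = "strict",
) -> str:
    """Light phase at a trip's start: day / night / dawn / dusk.

    ``night_definition="not_day"`` collapses dawn and dusk into night for
    day-versus-night tallies; the default keeps all four phases distinct.
    """
    if start_local.tzinfo is None:
        raise ValueError("start_local must be timezone-aware")
    tz_id = str(start_local.tzinfo)
    sd = solar_day(lat, lon, start_local.date(), tz_id=tz_id)
    phase = "night"
    if sd.sunrise is not None and sd.sunset is not None:
        if sd.sunrise <= start_local < sd.sunset:
            phase = "day"
        elif sd.civil_dawn is not None and sd.civil_dawn <= start_local < sd.sunrise:
            phase = "dawn"
        elif sd.civil_dusk is not None and sd.sunset <= start_local < sd.civil_dusk:
            phase = "dusk"
    else:
        # polar day or night: fall back to the sun's elevation at the instant
        elev = solar_elevation(lat, lon, start_local)
        if elev >= SUNRISE_ELEVATION:
            phase = "day"
        elif elev >= CIVIL_ELEVATION:
            # twilight without a same-date crossing; call it dusk by convention
            phase = "dusk"
    if night_definition == "not_day" and phase in ("dawn", "dusk"):
        return "night"
    return phase
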