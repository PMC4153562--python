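"""Coordinate projection and solar day/night classification.

Positions are projected from geographic (WGS84 lon/lat) to planar UTM
coordinates with a Krueger-series transverse Mercator implementation.
The whole study domain is projected into a single, fixed zone (default
zone 28, central meridian 15 deg W), matching the convention of using one
planar frame for the full region rather than per-point zone selection.

Day/night classification follows the civil-dawn convention: a sample is
"night" when the apparent solar elevation is 6 degrees or more below the
horizon, computed from a low-precision (< 0.5 deg) solar-position
algorithm.  All instants are UTC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "GeoPoint",
    "PlanePoint",
    "SolarContext",
    "DEFAULT_ZONE",
    "NIGHT_ELEVATION_DEG",
    "project",
    "unproject",
    "project_lonlat",
    "unproject_plane",
    "solar_elevation",
    "classify_daynight",
    "day_of_year_365",
]

DEFAULT_ZONE = 28
NIGHT_ELEVATION_DEG = -6.0

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500_000.0

_N = _F / (2.0 - _F)
# Rectifying radius
_A1 = _A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0)

# Krueger series coefficients (4th order in the third flattening n).
_ALPHA = np.array([
    _N / 2.0 - 2.0 / 3.0 * _N**2 + 5.0 / 16.0 * _N**3 + 41.0 / 180.0 * _N**4,
    13.0 / 48.0 * _N**2 - 3.0 / 5.0 * _N**3 + 557.0 / 1440.0 * _N**4,
    61.0 / 240.0 * _N**3 - 103.0 / 140.0 * _N**4,
    49561.0 / 161280.0 * _N**4,
])
_BETA = np.array([
    _N / 2.0 - 2.0 / 3.0 * _N**2 + 37.0 / 96.0 * _N**3 - 1.0 / 360.0 * _N**4,
    _N**2 / 48.0 + _N**3 / 15.0 - 437.0 / 1440.0 * _N**4,
    17.0 / 480.0 * _N**3 - 37.0 / 840.0 * _N**4,
    4397.0 / 161280.0 * _N**4,
])
# 2*sqrt(n)/(1+n), used in the conformal-latitude transform
_CONF_K = 2.0 * np.sqrt(_N) / (1.0 + _N)


@dataclass(frozen=True)
class GeoPoint:
    """A geographic position in degrees (WGS84)."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise ValueError("lon/lat must be finite")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class PlanePoint:
    """A projected planar position in metres (UTM easting/northing)."""

    east: float
    north: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.east) and np.isfinite(self.north)):
            raise ValueError("east/north must be finite")


@dataclass(frozen=True)
class SolarContext:
    """Solar geometry at one instant and position."""

    instant: pd.Timestamp
    point: GeoPoint
    elevation: float
    dn: str

    def __post_init__(self) -> None:
        expected = classify_daynight(self.elevation)
        if self.dn != expected:
            raise ValueError(
                f"dn={self.dn!r} inconsistent with elevation {self.elevation}"
            )


def _validate_zone(zone: int) -> float:
    if not (isinstance(zone, (int, np.integer)) and 1 <= zone <= 60):
        raise ValueError(f"UTM zone must be an integer in 1..60, got {zone!r}")
    return float(-183 + 6 * zone)  # central meridian, degrees


def project_lonlat(lon, lat, zone: int = DEFAULT_ZONE):
    """Project lon/lat arrays (degrees) to UTM easting/northing (metres).

    Uses the northern-hemisphere convention (no false northing).
    """
    lon0 = _validate_zone(zone)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise ValueError("lon/lat must be finite")
    if np.any(lat < -80.0) or np.any(lat > 84.0):
        raise ValueError(
            "latitude outside the transverse-Mercator validity range [-80, 84]"
        )

    phi = np.radians(lat)
    lam = np.radians(lon - lon0)

    sphi = np.sin(phi)
    t = np.sinh(np.arctanh(sphi) - _CONF_K * np.arctanh(_CONF_K * sphi))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arctanh(np.sin(lam) / np.sqrt(1.0 + t * t))

    xi = xi_p.copy()
    eta = eta_p.copy()
    for j, (aj,) in enumerate(zip(_ALPHA), start=1):
        xi = xi + aj * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta = eta + aj * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)

    east = _FALSE_EASTING + _K0 * _A1 * eta
    north = _K0 * _A1 * xi
    return east, north


def unproject_plane(east, north, zone: int = DEFAULT_ZONE):
    """Invert :func:`project_lonlat`; returns (lon, lat) in degrees."""
    lon0 = _validate_zone(zone)
    east = np.asarray(east, dtype=float)
    north = np.asarray(north, dtype=float)

    xi = north / (_K0 * _A1)
    eta = (east - _FALSE_EASTING) / (_K0 * _A1)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, (bj,) in enumerate(zip(_BETA), start=1):
        xi_p = xi_p - bj * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p = eta_p - bj * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    t = np.sin(xi_p) / np.sqrt(np.sinh(eta_p) ** 2 + np.cos(xi_p) ** 2)
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    # Invert the conformal-latitude transform by Newton iteration on sin(phi).
    chi = np.arctan(t)
    phi = chi + (
        (2.0 * _N - 2.0 / 3.0 * _N**2 - 2.0 * _N**3) * np.sin(2 * chi)
        + (7.0 / 3.0 * _N**2 - 8.0 / 5.0 * _N**3) * np.sin(4 * chi)
        + 56.0 / 15.0 * _N**3 * np.sin(6 * chi)
    )
    for _ in range(4):
        sphi = np.sin(phi)
        g = np.arctanh(sphi) - _CONF_K * np.arctanh(_CONF_K * sphi)
        f = np.sinh(g) - t
        dg = 1.0 / np.cos(phi) - _CONF_K**2 * np.cos(phi) / (
            1.0 - (_CONF_K * sphi) ** 2
        )
        phi = phi - f / (np.cosh(g) * dg)

    lat = np.degrees(phi)
    lon = lon0 + np.degrees(lam)
    return lon, lat


def project(p: GeoPoint, zone: int = DEFAULT_ZONE) -> PlanePoint:
    """Project a single geographic point to the plane."""
    east, north = project_lonlat(p.lon, p.lat, zone)
    return PlanePoint(east=float(east), north=float(north))


def unproject(p: PlanePoint, zone: int = DEFAULT_ZONE) -> GeoPoint:
    """Inverse projection of a single planar point."""
    lon, lat = unproject_plane(p.east, p.north, zone)
    return GeoPoint(lon=float(lon), lat=float(lat))


# ---------------------------------------------------------------------------
# Solar position (NOAA low-precision algorithm; no refraction correction)
# ---------------------------------------------------------------------------

def _julian_century(instant) -> np.ndarray:
    ts = pd.to_datetime(instant, utc=True)
    if isinstance(ts, pd.Timestamp):
        ts = pd.DatetimeIndex([ts])
    else:
        ts = pd.DatetimeIndex(ts)
    years = ts.year
    if (years < 1900).any() or (years > 2100).any():
        raise ValueError("instants must lie within 1900-2100")
    # Days since J2000.0 epoch (2000-01-01 12:00 UTC)
    epoch = pd.Timestamp("2000-01-01 12:00:00", tz="UTC")
    days = (ts - epoch) / pd.Timedelta(days=1)
    return np.asarray(days, dtype=float) / 36525.0


def _solar_decl_eot(T: np.ndarray):
    """Solar declination (radians) and equation of time (minutes)."""
    L0 = np.radians((280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0)
    M = np.radians(357.52911 + T * (35999.05029 - 0.0001537 * T))
    ecc = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    C = (
        np.sin(M) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * M) * (0.019993 - 0.000101 * T)
        + np.sin(3 * M) * 0.000289
    )
    true_long = np.degrees(L0) + C
    omega = np.radians(125.04 - 1934.136 * T)
    app_long = np.radians(true_long - 0.00569 - 0.00478 * np.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(eps) * np.sin(app_long))

    y = np.tan(eps / 2.0) ** 2
    eot = 4.0 * np.degrees(
        y * np.sin(2 * L0)
        - 2.0 * ecc * np.sin(M)
        + 4.0 * ecc * y * np.sin(M) * np.cos(2 * L0)
        - 0.5 * y * y * np.sin(4 * L0)
        - 1.25 * ecc * ecc * np.sin(2 * M)
    )
    return decl, eot


def solar_elevation(instant, lon, lat) -> Union[float, np.ndarray]:
    """Apparent solar elevation in degrees at UTC instant(s) and position(s).

    Accepts scalars or aligned arrays; accuracy is ~0.1-0.5 degrees, which
    is sufficient for a -6 degree day/night threshold.  Refraction is not
    modelled.
    """
    scalar = np.isscalar(lon) and not isinstance(
        instant, (pd.DatetimeIndex, pd.Series, np.ndarray, list, tuple)
    )
    T = _julian_century(instant)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    decl, eot = _solar_decl_eot(T)

    ts = pd.to_datetime(instant, utc=True)
    if isinstance(ts, pd.Timestamp):
        ts = pd.DatetimeIndex([ts])
    else:
        ts = pd.DatetimeIndex(ts)
    minutes = (
        np.asarray(ts.hour, dtype=float) * 60.0
        + np.asarray(ts.minute, dtype=float)
        + np.asarray(ts.second, dtype=float) / 60.0
        + np.asarray(ts.microsecond, dtype=float) / 6.0e7
    )
    tst = np.mod(minutes + eot + 4.0 * lon, 1440.0)
    ha = np.radians(tst / 4.0 - 180.0)

    phi = np.radians(lat)
    sin_el = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    elev = np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0)))
    if scalar:
        return float(elev[0])
    return elev


def classify_daynight(elevation) -> Union[str, np.ndarray]:
    """Classify solar elevation(s) as ``"day"`` or ``"night"``.

    Night is elevation <= -6 degrees (civil-dawn convention, inclusive);
    civil twilight counts as day.
    """
    arr = np.asarray(elevation, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("elevation must be finite")
    out = np.where(arr <= NIGHT_ELEVATION_DEG, "night", "day")
    if np.isscalar(elevation) or arr.ndim == 0:
        return str(out[()])
    return out


def solar_context(instant, p: GeoPoint) -> SolarContext:
    """Bundle elevation and day/night state for one observation."""
    elev = solar_elevation(instant, p.lon, p.lat)
    return SolarContext(
        instant=pd.Timestamp(instant, tz="UTC") if pd.Timestamp(instant).tz is None
        else pd.Timestamp(instant),
        point=p,
        elevation=float(elev),
        dn=classify_daynight(elev),
    )


def day_of_year_365(instant) -> Union[int, np.ndarray]:
    """Day of year on a fixed 365-day axis; Feb 29 maps to day 60.

    In leap years, days after Feb 29 are shifted down by one so that the
    axis is comparable across years (period 365).
    """
    ts = pd.to_datetime(instant, utc=True)
    scalar = isinstance(ts, pd.Timestamp)
    ts = pd.DatetimeIndex([ts] if scalar else ts)
    doy = np.asarray(ts.dayofyear, dtype=int)
    leap = np.asarray(ts.is_leap_year) & (doy > 60)
    doy = np.where(leap, doy - 1, doy)
    if scalar:
        return int(doy[0])
    return doy
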