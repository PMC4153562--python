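"""Recorder-like survey simulator with a known two-component truth.

The generator emulates the essential features of a ship-of-opportunity
plankton survey: fixed transect routes sampled in ~10-nautical-mile
segments, a within-month sampling-intensity cycle, year-dependent route
coverage, rare presences (~2%), two spatially and seasonally separated
spawning components with distinct interannual trends, and a day/night
catchability offset.

The truth surface is built from Gaussian bumps in projected space and
Gaussian seasonal windows on a circular day-of-year axis; downstream
fitters see only the sampled presence/absence records, never this form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import geo_time
from .geo_time import DEFAULT_ZONE, GeoPoint, PlanePoint

__all__ = [
    "SpawningComponent",
    "TruthConfig",
    "SamplingDesign",
    "AbundanceCategoryScheme",
    "truth_probability",
    "generate_samples",
    "simulate_observations",
    "default_truth",
    "default_design",
    "write_truth_sidecar",
    "DOY_PERIOD",
    "NMI_M",
]

DOY_PERIOD = 365.0
NMI_M = 1852.0
_EARTH_R_M = 6371008.8

YearTrend = Union[Mapping[int, float], Callable[[np.ndarray], np.ndarray], None]


def circular_doy_distance(doy, peak, period: float = DOY_PERIOD):
    """Shortest distance between days on a circular axis."""
    d = np.abs(np.asarray(doy, dtype=float) - float(peak)) % period
    return np.minimum(d, period - d)


@dataclass
class SpawningComponent:
    """One Gaussian spawning centre with a seasonal window and year trend."""

    center: PlanePoint
    spatial_sd: float       # metres, isotropic
    peak_doy: float
    seasonal_sd: float      # days
    amplitude: float        # logit units at centre/peak
    year_trend: YearTrend = None
    name: str = "component"

    def __post_init__(self) -> None:
        if not 1 <= self.peak_doy <= 366:
            raise ValueError("peak_doy must lie in [1, 366]")
        if self.spatial_sd <= 0 or self.seasonal_sd <= 0:
            raise ValueError("spatial_sd and seasonal_sd must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")

    def trend_at(self, year) -> np.ndarray:
        year = np.asarray(year)
        if self.year_trend is None:
            return np.zeros(year.shape, dtype=float)
        if callable(self.year_trend):
            out = np.asarray(self.year_trend(year), dtype=float)
        else:
            out = np.asarray(
                [self.year_trend.get(int(y), 0.0) for y in np.atleast_1d(year)],
                dtype=float,
            ).reshape(year.shape)
        if not np.all(np.isfinite(out)):
            raise ValueError("year trend produced non-finite offsets")
        return out

    def logit_contribution(self, east, north, doy, year) -> np.ndarray:
        r2 = (np.asarray(east, float) - self.center.east) ** 2 + (
            np.asarray(north, float) - self.center.north
        ) ** 2
        dd = circular_doy_distance(doy, self.peak_doy)
        bump = np.exp(-r2 / (2.0 * self.spatial_sd**2)) * np.exp(
            -(dd**2) / (2.0 * self.seasonal_sd**2)
        )
        return (self.amplitude + self.trend_at(year)) * bump


@dataclass
class TruthConfig:
    """The known generating process behind a synthetic dataset."""

    components: list[SpawningComponent]
    dn_effect: float            # logit offset added for daytime samples
    years: tuple[int, int]      # inclusive range
    base_logit: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one spawning component is required")
        if self.years[0] > self.years[1]:
            raise ValueError("years must be an inclusive (first, last) range")
        for v in (self.dn_effect, self.base_logit):
            if not np.isfinite(v):
                raise ValueError("dn_effect and base_logit must be finite")
        # Reject configurations whose implied probabilities can saturate to
        # exactly 0 or 1 in double precision.
        yrs = np.arange(self.years[0], self.years[1] + 1)
        worst = abs(self.base_logit) + abs(self.dn_effect)
        for c in self.components:
            worst += abs(c.amplitude) + float(np.max(np.abs(c.trend_at(yrs))))
        if worst > 700.0:
            raise ValueError("configuration implies probabilities outside (0, 1)")

    @property
    def year_list(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)


def truth_probability(cfg: TruthConfig, x, doy, year, dn) -> np.ndarray:
    """True occurrence probability at planar position(s) ``x``.

    ``x`` is a PlanePoint or an ``(east, north)`` pair of arrays; ``dn``
    is ``"day"``/``"night"`` (scalar or array).  The day/night offset is
    applied to daytime samples (night is the reference level).
    """
    if isinstance(x, PlanePoint):
        east, north = np.asarray(x.east), np.asarray(x.north)
    else:
        east, north = np.asarray(x[0], float), np.asarray(x[1], float)
    doy = np.asarray(doy, dtype=float)
    if np.any(doy < 1) or np.any(doy > 366):
        raise ValueError("doy must lie in [1, 366]")
    year = np.asarray(year)
    y0, y1 = cfg.years
    if np.any((year < y0) | (year > y1)):
        raise ValueError(f"year outside configured range {cfg.years}")

    eta = np.full(np.broadcast(east, north, doy, year).shape, cfg.base_logit, dtype=float)
    for comp in cfg.components:
        eta = eta + comp.logit_contribution(east, north, doy, year)
    is_day = np.asarray(dn) == "day"
    eta = eta + cfg.dn_effect * is_day
    p = 1.0 / (1.0 + np.exp(-eta))
    return p if p.shape else float(p)


# ---------------------------------------------------------------------------
# Sampling design
# ---------------------------------------------------------------------------

@dataclass
class SamplingDesign:
    """Fixed transect routes and their temporal sampling pattern."""

    routes: list[np.ndarray]                  # each (m, 2) array of (lon, lat)
    segment_nmi: float = 10.0
    monthly_weight: Optional[np.ndarray] = None   # relative weight per day-of-month slot
    route_years: Optional[list[Optional[tuple[int, int]]]] = None  # inclusive ranges
    tow_speed_kn: float = 10.0

    def __post_init__(self) -> None:
        if self.segment_nmi <= 0:
            raise ValueError("segment_nmi must be positive")
        self.routes = [np.asarray(r, dtype=float) for r in self.routes]
        for r in self.routes:
            if r.ndim != 2 or r.shape[1] != 2 or r.shape[0] < 2:
                raise ValueError("each route must be an (m>=2, 2) lon/lat polyline")
        if self.monthly_weight is None:
            # triangular profile peaking mid-month (28 within-month slots)
            s = np.arange(28, dtype=float)
            self.monthly_weight = 1.0 + 2.0 * (1.0 - np.abs(s - 13.5) / 13.5)
        self.monthly_weight = np.asarray(self.monthly_weight, dtype=float)
        if np.any(self.monthly_weight < 0) or self.monthly_weight.sum() <= 0:
            raise ValueError("monthly_weight must be non-negative with positive sum")
        if self.route_years is not None and len(self.route_years) != len(self.routes):
            raise ValueError("route_years must align with routes")

    def active(self, route_idx: int, year: int) -> bool:
        if self.route_years is None or self.route_years[route_idx] is None:
            return True
        y0, y1 = self.route_years[route_idx]
        return y0 <= year <= y1


def _haversine_nmi(lon1, lat1, lon2, lat2) -> float:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2.0 * _EARTH_R_M * np.arcsin(np.sqrt(a)) / NMI_M


def _route_points(route: np.ndarray, segment_nmi: float):
    """Sample-segment midpoints (lon, lat, along-track nmi) along a polyline."""
    seglen = np.array(
        [
            _haversine_nmi(route[i, 0], route[i, 1], route[i + 1, 0], route[i + 1, 1])
            for i in range(len(route) - 1)
        ]
    )
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    n_pts = int(np.floor(total / segment_nmi + 1e-9))
    s = (np.arange(n_pts) + 0.5) * segment_nmi
    s = s[s < total]
    idx = np.searchsorted(cum, s, side="right") - 1
    idx = np.clip(idx, 0, len(seglen) - 1)
    frac = (s - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    lon = route[idx, 0] + frac * (route[idx + 1, 0] - route[idx, 0])
    lat = route[idx, 1] + frac * (route[idx + 1, 1] - route[idx, 1])
    return lon, lat, s


def generate_samples(
    design: SamplingDesign, years: Sequence[int], seed: int = 0
) -> pd.DataFrame:
    """Emit sampling positions and instants for every active route-month.

    Each active route is traversed once per month; samples are placed at
    segment midpoints every ``segment_nmi`` along the polyline.  The
    traversal start day is drawn from ``monthly_weight`` and sample
    instants advance along-track at ``tow_speed_kn``.  Deterministic for
    a given seed.
    """
    rng = np.random.default_rng(seed)
    rows: dict[str, list] = {"lon": [], "lat": [], "instant": [], "route": []}
    w = design.monthly_weight / design.monthly_weight.sum()
    nslots = len(w)
    for ri, route in enumerate(design.routes):
        lon, lat, s_nmi = _route_points(route, design.segment_nmi)
        if lon.size == 0:
            continue
        hours = s_nmi / design.tow_speed_kn
        for year in years:
            if not design.active(ri, int(year)):
                continue
            for month in range(1, 13):
                days_in_month = pd.Timestamp(int(year), month, 1).days_in_month
                slot = rng.choice(nslots, p=w)
                day = 1 + int(slot * days_in_month / nslots)
                start_hour = rng.uniform(0.0, 24.0)
                t0 = pd.Timestamp(int(year), month, day, tz="UTC") + pd.Timedelta(
                    hours=start_hour
                )
                inst = t0 + pd.to_timedelta(hours, unit="h")
                rows["lon"].extend(lon.tolist())
                rows["lat"].extend(lat.tolist())
                rows["instant"].extend(inst)
                rows["route"].extend([ri] * lon.size)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["instant"] = pd.DatetimeIndex(df["instant"])
    return df


# ---------------------------------------------------------------------------
# Abundance categories
# ---------------------------------------------------------------------------

@dataclass
class AbundanceCategoryScheme:
    """Ordered abundance categories with inclusive count ranges."""

    labels: list[str] = field(
        default_factory=lambda: ["0", "1", "2", "3", "4-11", "12-25"]
    )
    ranges: list[tuple[int, int]] = field(
        default_factory=lambda: [(0, 0), (1, 1), (2, 2), (3, 3), (4, 11), (12, 25)]
    )

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.ranges):
            raise ValueError("labels and ranges must align")
        prev_hi = -1
        for lo, hi in self.ranges:
            if lo != prev_hi + 1 or hi < lo:
                raise ValueError("ranges must be contiguous, non-overlapping, increasing")
            prev_hi = hi

    @property
    def max_count(self) -> int:
        return self.ranges[-1][1]

    def category_for(self, count: int, clip: bool = True) -> str:
        if count < 0:
            raise ValueError("count must be non-negative")
        if count > self.max_count:
            if not clip:
                raise ValueError(f"count {count} beyond top category")
            return self.labels[-1]
        for lab, (lo, hi) in zip(self.labels, self.ranges):
            if lo <= count <= hi:
                return lab
        raise AssertionError("unreachable: contiguous ranges")

    def range_for(self, label: str) -> tuple[int, int]:
        try:
            return self.ranges[self.labels.index(label)]
        except ValueError:
            raise ValueError(f"unknown category label {label!r}") from None


def simulate_observations(
    cfg: TruthConfig,
    samples: pd.DataFrame,
    seed: int = 0,
    scheme: Optional[AbundanceCategoryScheme] = None,
    geometric_p: float = 0.45,
    zone: int = DEFAULT_ZONE,
) -> pd.DataFrame:
    """Thin sampling positions through the truth into categorical records.

    Presence is Bernoulli(truth probability); presences receive a
    geometric count (>= 1) mapped through the category scheme, absences
    category "0".  Returns a table with positions, instants, derived
    covariates and categories.
    """
    scheme = scheme or AbundanceCategoryScheme()
    rng = np.random.default_rng(seed)
    df = samples.copy().reset_index(drop=True)
    if df.empty:
        return df.assign(category_label=pd.Series(dtype=str))
    east, north = geo_time.project_lonlat(df["lon"].to_numpy(), df["lat"].to_numpy(), zone)
    elev = geo_time.solar_elevation(
        df["instant"], df["lon"].to_numpy(), df["lat"].to_numpy()
    )
    dn = geo_time.classify_daynight(elev)
    doy = geo_time.day_of_year_365(df["instant"])
    year = pd.DatetimeIndex(df["instant"]).year.to_numpy()

    p = truth_probability(cfg, (east, north), doy, year, dn)
    present = rng.uniform(size=len(df)) < p
    counts = np.zeros(len(df), dtype=int)
    n_pres = int(present.sum())
    if n_pres:
        counts[present] = rng.geometric(geometric_p, size=n_pres)
    labels = np.array([scheme.category_for(int(c)) for c in counts])

    df["east"] = east
    df["north"] = north
    df["solar_elev_deg"] = elev
    df["dn"] = dn
    df["doy"] = doy
    df["year"] = year
    df["present"] = present.astype(int)
    df["category_label"] = labels
    df["true_p"] = p
    return df


# ---------------------------------------------------------------------------
# Defaults: a stock-like two-component configuration
# ---------------------------------------------------------------------------

def default_truth(seed: int = 0) -> TruthConfig:
    """A two-component truth with ~2% overall presences under
    :func:`default_design` sampling.

    Southern centre off-shelf near 49.5N with seasonal peak at day 80;
    northern centre in the deep-trough analogue near 56.5N peaking at day
    120 (a 40-day offset); amplitudes differ so the southern integrated
    abundance is the smaller; distinct year trends per component; +0.17
    logit daytime catchability offset.
    """
    south_center = geo_time.project(GeoPoint(lon=-12.0, lat=49.5))
    north_center = geo_time.project(GeoPoint(lon=-9.5, lat=56.5))

    def south_trend(year):
        y = np.asarray(year, dtype=float)
        return 0.6 * np.sin(2.0 * np.pi * (y - 1950.0) / 30.0)

    def north_trend(year):
        y = np.asarray(year, dtype=float)
        return 0.025 * (y - 1962.0)

    return TruthConfig(
        components=[
            SpawningComponent(
                center=south_center,
                spatial_sd=200_000.0,
                peak_doy=80.0,
                seasonal_sd=28.0,
                amplitude=5.5,
                year_trend=south_trend,
                name="south",
            ),
            SpawningComponent(
                center=north_center,
                spatial_sd=220_000.0,
                peak_doy=120.0,
                seasonal_sd=32.0,
                amplitude=6.2,
                year_trend=north_trend,
                name="north",
            ),
        ],
        dn_effect=0.17,
        years=(1950, 2000),
        base_logit=-5.5,
        seed=seed,
    )


def default_design() -> SamplingDesign:
    """Ship-of-opportunity route network with quasi-2-D coverage.

    Fans of transect lines from three hub ports plus meridional
    weather-ship lines and two subarctic routes: coverage is dense
    enough that the spatial field is constrained away from the tracks
    themselves.  One route through the deep-trough analogue is retired
    after 1974 (emulating the reduced later coverage of that region).
    """
    routes: list[np.ndarray] = []
    route_years: list = []
    # Channel hub fanning west across the southern grounds
    for lat_end in (46.5, 48.5, 50.5, 52.5):
        routes.append(np.array([[-5.5, 49.5], [-19.5, lat_end]]))
        route_years.append(None)
    # Irish Sea hub fanning west/north-west
    for lat_end in (50.5, 53.0, 55.5, 58.0):
        routes.append(np.array([[-6.0, 52.0], [-19.0, lat_end]]))
        route_years.append(None)
    # Clyde hub fanning across the trough region
    for lat_end in (54.5, 56.5, 58.5):
        routes.append(np.array([[-6.0, 55.5], [-17.5, lat_end]]))
        route_years.append((1948, 1974) if lat_end == 56.5 else None)
    # subarctic routes through the north-west
    routes.append(np.array([[-6.5, 57.5], [-14.0, 59.5], [-21.0, 62.0]]))
    route_years.append(None)
    routes.append(np.array([[-8.0, 54.0], [-14.0, 58.0], [-20.0, 61.0]]))
    route_years.append(None)
    # meridional weather-ship lines
    for line in ([[-11.0, 46.5], [-11.5, 60.5]],
                 [[-15.5, 47.0], [-15.0, 61.0]],
                 [[-19.0, 50.0], [-18.5, 61.5]]):
        routes.append(np.array(line))
        route_years.append(None)
    # shelf routes pinning the north-east and south-east corners
    routes.append(np.array([[-2.5, 61.0], [-7.0, 58.5], [-10.0, 56.5]]))
    route_years.append(None)
    routes.append(np.array([[-5.0, 48.0], [-8.0, 46.0], [-12.0, 45.5]]))
    route_years.append(None)
    return SamplingDesign(routes=routes, segment_nmi=10.0, route_years=route_years)


def write_truth_sidecar(cfg: TruthConfig, path) -> None:
    """Record the truth parameters as plain-text key-value lines."""
    lines = [
        f"base_logit: {cfg.base_logit}",
        f"dn_effect: {cfg.dn_effect}",
        f"years: {cfg.years[0]}-{cfg.years[1]}",
        f"seed: {cfg.seed}",
        f"n_components: {len(cfg.components)}",
    ]
    for i, c in enumerate(cfg.components):
        lines += [
            f"component{i}.name: {c.name}",
            f"component{i}.center_east_m: {c.center.east}",
            f"component{i}.center_north_m: {c.center.north}",
            f"component{i}.spatial_sd_m: {c.spatial_sd}",
            f"component{i}.peak_doy: {c.peak_doy}",
            f"component{i}.seasonal_sd_days: {c.seasonal_sd}",
            f"component{i}.amplitude_logit: {c.amplitude}",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
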