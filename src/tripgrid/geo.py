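"""Telemetry feature extraction from raw GPS fixes.

Converts per-second latitude/longitude fixes into the tabular ("naive")
feature set used by the classifiers: step distance (km, haversine), speed
(kph, central difference), speed over ground (kph, device-reported or
imputed), and direction expressed both as a compass azimuth and as its
unit-circle components (azimuth_x, azimuth_y).

The unit-circle mapping removes the 0/360 discontinuity of compass
bearings: North maps to (0, 1), East to (1, 0), South to (0, -1), West to
(-1, 0). A point with no defined heading (trip end, or no displacement)
carries the sentinel (0, 0), which is distinguishable because every defined
heading has unit norm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "EarthModel",
    "GpsFix",
    "TelemetryRecord",
    "UndefinedBearingError",
    "haversine_distance",
    "central_speed",
    "bearing",
    "azimuth_to_unit_circle",
    "build_feature_table",
    "featurize_frame",
]


class UndefinedBearingError(ValueError):
    """Raised when a bearing is requested between coincident points."""


@dataclass(frozen=True)
class EarthModel:
    """Spherical Earth with configurable radius (km)."""

    radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if not (self.radius_km > 0 and math.isfinite(self.radius_km)):
            raise ValueError(f"radius_km must be positive and finite, got {self.radius_km}")


DEFAULT_EARTH = EarthModel()


@dataclass(frozen=True)
class GpsFix:
    """One timestamped GPS sample.

    timestamp is seconds since trip start (1 Hz nominal); lat/lon in degrees.
    """

    timestamp: float
    lat: float
    lon: float

    def __post_init__(self) -> None:
        for name, v in (("timestamp", self.timestamp), ("lat", self.lat), ("lon", self.lon)):
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range [-90, 90]: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon out of range [-180, 180]: {self.lon}")


@dataclass(frozen=True)
class TelemetryRecord:
    """A GpsFix enriched with derived motion features.

    azimuth is NaN (and the unit-circle components are the (0, 0) sentinel)
    where no heading is defined. sog_imputed marks SOG values filled in from
    the computed speed rather than reported by the device.
    """

    fix: GpsFix
    step_distance_km: float
    speed_kph: float
    sog_kph: float
    azimuth_deg: float
    azimuth_x: float
    azimuth_y: float
    sog_imputed: bool = field(default=False, compare=False)


def _hav_arrays(lat1, lon1, lat2, lon2, radius_km: float):
    """Vectorized haversine great-circle distance (km) on a sphere."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _bearing_arrays(lat1, lon1, lat2, lon2):
    """Vectorized forward azimuth in degrees [0, 360); 0 = North, clockwise."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(lon2) - np.radians(lon1)
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    az = np.degrees(np.arctan2(y, x)) % 360.0
    # float rounding of tiny negative angles can land exactly on 360
    return np.where(az >= 360.0, 0.0, az)


def haversine_distance(a: GpsFix, b: GpsFix, earth: EarthModel = DEFAULT_EARTH) -> float:
    """Great-circle distance between two fixes in km.

    Symmetric in its arguments and bounded by pi * radius (antipodal).
    """
    return float(_hav_arrays(a.lat, a.lon, b.lat, b.lon, earth.radius_km))


def central_speed(p1: GpsFix, p3: GpsFix, earth: EarthModel = DEFAULT_EARTH) -> float:
    """Speed (kph) at the midpoint of p1..p3 by central difference.

    Distance between the flanking fixes divided by their time interval;
    the result is conventionally assigned to the middle point p2.
    """
    dt = p3.timestamp - p1.timestamp
    if dt <= 0:
        raise ValueError(f"time interval must be positive, got {dt} s")
    return haversine_distance(p1, p3, earth) / dt * 3600.0


def bearing(a: GpsFix, b: GpsFix) -> float:
    """Forward azimuth from a to b in degrees [0, 360); 0 = North, 90 = East."""
    if a.lat == b.lat and a.lon == b.lon:
        raise UndefinedBearingError("bearing undefined for coincident points")
    return float(_bearing_arrays(a.lat, a.lon, b.lat, b.lon))


def azimuth_to_unit_circle(azimuth_deg: float) -> tuple[float, float]:
    """Map a compass azimuth onto the unit circle: (sin az, cos az).

    North (0 or 360 degrees) maps to (0, 1), East to (1, 0), South to
    (0, -1), West to (-1, 0); the mapping is continuous across North.
    """
    th = math.radians(azimuth_deg)
    x, y = math.sin(th), math.cos(th)
    # snap values that are exactly cardinal in degrees, so 0 and 360 agree bitwise
    if azimuth_deg % 90.0 == 0.0:
        x, y = round(x), round(y)
    return float(x), float(y)


def featurize_frame(
    trip: pd.DataFrame, earth: EarthModel = DEFAULT_EARTH
) -> pd.DataFrame:
    """Vectorized feature extraction for one trip.

    ``trip`` needs columns ``timestamp, lat, lon`` and optionally ``sog_kph``
    (blank/NaN entries are imputed from the computed speed). Returns a copy
    with ``step_distance_km, speed_kph, sog_kph, azimuth_deg, azimuth_x,
    azimuth_y, sog_imputed`` columns added. Requires >= 3 rows with strictly
    increasing timestamps.
    """
    n = len(trip)
    if n < 3:
        raise ValueError(f"trip too short: {n} fixes (need >= 3)")
    t = trip["timestamp"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing within a trip")
    lat = trip["lat"].to_numpy(dtype=float)
    lon = trip["lon"].to_numpy(dtype=float)

    # step distance to the next fix; last point has no successor -> 0
    step = np.zeros(n)
    step[:-1] = _hav_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:], earth.radius_km)

    # central-difference speed; one-sided at the endpoints
    speed = np.empty(n)
    d13 = _hav_arrays(lat[:-2], lon[:-2], lat[2:], lon[2:], earth.radius_km)
    speed[1:-1] = d13 / (t[2:] - t[:-2]) * 3600.0
    speed[0] = step[0] / (t[1] - t[0]) * 3600.0
    speed[-1] = step[-2] / (t[-1] - t[-2]) * 3600.0

    # heading toward the next fix; sentinel where there is no displacement
    az = np.full(n, np.nan)
    moved = (lat[:-1] != lat[1:]) | (lon[:-1] != lon[1:])
    az[:-1][moved] = _bearing_arrays(
        lat[:-1][moved], lon[:-1][moved], lat[1:][moved], lon[1:][moved]
    )
    defined = np.isfinite(az)
    ax = np.zeros(n)
    ay = np.zeros(n)
    ax[defined] = np.sin(np.radians(az[defined]))
    ay[defined] = np.cos(np.radians(az[defined]))
    cardinal = defined & (np.mod(az, 90.0) == 0.0)
    ax[cardinal] = np.round(ax[cardinal])
    ay[cardinal] = np.round(ay[cardinal])

    out = trip.copy()
    out["step_distance_km"] = step
    out["speed_kph"] = speed
    if "sog_kph" in out.columns:
        sog = pd.to_numeric(out["sog_kph"], errors="coerce").to_numpy(dtype=float)
    else:
        sog = np.full(n, np.nan)
    imputed = ~np.isfinite(sog)
    sog = np.where(imputed, speed, sog)
    out["sog_kph"] = sog
    out["sog_imputed"] = imputed
    out["azimuth_deg"] = az
    out["azimuth_x"] = ax
    out["azimuth_y"] = ay
    return out


def build_feature_table(
    trip: Sequence[GpsFix],
    sog: Sequence[float] | None = None,
    earth: EarthModel = DEFAULT_EARTH,
) -> list[TelemetryRecord]:
    """Build one TelemetryRecord per fix of a trip.

    Endpoint speeds use one-sided differences; the last fix (and any fix with
    no displacement to its successor) carries the azimuth sentinel (0, 0).
    Missing SOG entries are imputed from the computed speed and flagged.
    """
    df = pd.DataFrame(
        {
            "timestamp": [f.timestamp for f in trip],
            "lat": [f.lat for f in trip],
            "lon": [f.lon for f in trip],
        }
    )
    if sog is not None:
        if len(sog) != len(trip):
            raise ValueError("sog length must match trip length")
        df["sog_kph"] = [math.nan if s is None else s for s in sog]
    feats = featurize_frame(df, earth)
    return [
        TelemetryRecord(
            fix=fix,
            step_distance_km=float(r.step_distance_km),
            speed_kph=float(r.speed_kph),
            sog_kph=float(r.sog_kph),
            azimuth_deg=float(r.azimuth_deg),
            azimuth_x=float(r.azimuth_x),
            azimuth_y=float(r.azimuth_y),
            sog_imputed=bool(r.sog_imputed),
        )
        for fix, r in zip(trip, feats.itertuples())
    ]
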