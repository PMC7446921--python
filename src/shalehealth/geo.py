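"""Proximity-based exposure metrics around a residence.

Distances are great-circle (haversine) on a sphere with the IUGG mean Earth
radius.  The two proximity metrics follow the conventions used in studies of
unconventional oil and gas development (UOGD):

* cumulative well density (CWD) — wells within a buffer radius divided by the
  buffer area, in wells/km²;
* inverse distance weighting (IDW) — ``sum(1/d_i)`` over wells within the
  buffer, in km⁻¹, so nearer wells weigh more.

Also provided: directional-quadrant assignment (used by the dispersion
module) and the circular-segment fraction of a buffer clipped by a straight
administrative boundary, useful for auditing how much of a buffer falls
outside the state supplying the well inventory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

#: Distance floor (km) applied to wells nearer than 100 m in the IDW sum,
#: preventing unbounded scores from co-located coordinates.
IDW_FLOOR_KM = 0.1

WELL_COLUMNS = ["well_id", "lat", "lon", "year", "co_tpy", "nox_tpy", "pm25_tpy", "voc_tpy"]

__all__ = [
    "EARTH_RADIUS_KM",
    "IDW_FLOOR_KM",
    "WELL_COLUMNS",
    "haversine_km",
    "initial_bearing_deg",
    "quadrant_of",
    "wells_within_radius",
    "cwd",
    "idw_score",
    "buffer_clip_fraction",
    "read_well_table",
]


def _check_latlon(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")


def haversine_km(p1, p2):
    """Great-circle distance in km between ``(lat, lon)`` points.

    Accepts scalars or arrays (broadcast); coordinates are decimal degrees
    WGS84.  Symmetric and non-negative by construction.
    """
    lat1, lon1 = p1
    lat2, lon2 = p2
    _check_latlon(lat1, lon1)
    _check_latlon(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def initial_bearing_deg(p1, p2):
    """Initial bearing from ``p1`` to ``p2`` in degrees clockwise from north, in [0, 360)."""
    lat1, lon1 = p1
    lat2, lon2 = p2
    _check_latlon(lat1, lon1)
    _check_latlon(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlmb = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dlmb) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlmb)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    if np.ndim(theta) == 0:
        return float(theta)
    return theta


def pairwise_distances_km(homes, wells_latlon) -> np.ndarray:
    """Distance matrix (n_homes × n_wells) in km between two point sets.

    ``homes`` and ``wells_latlon`` are ``(lat_array, lon_array)`` pairs.
    """
    hlat, hlon = (np.asarray(a, dtype=float) for a in homes)
    wlat, wlon = (np.asarray(a, dtype=float) for a in wells_latlon)
    return haversine_km(
        (hlat[:, None], hlon[:, None]), (wlat[None, :], wlon[None, :])
    )


def quadrant_of(home, well) -> str:
    """Directional quadrant of ``well`` as seen from ``home``.

    The initial bearing is binned half-open: [0°, 90°) → NE, [90°, 180°) → SE,
    [180°, 270°) → SW, [270°, 360°) → NW, so due north falls in NE and due
    west in NW.

    Raises ``ValueError`` for coincident points (the bearing is undefined).
    """
    if float(home[0]) == float(well[0]) and float(home[1]) == float(well[1]):
        raise ValueError("quadrant undefined for coincident points")
    b = initial_bearing_deg(home, well)
    return ("NE", "SE", "SW", "NW")[int(b // 90.0) % 4]


def wells_within_radius(home, wells: pd.DataFrame, radius_km: float, year: int | None = None) -> pd.DataFrame:
    """Wells within ``radius_km`` (inclusive) of ``home``, annotated with distance.

    Parameters
    ----------
    home : (lat, lon)
        Residence coordinates in decimal degrees.
    wells : DataFrame
        Well table with at least ``lat``, ``lon`` and (if ``year`` given)
        ``year`` columns.
    radius_km : float
        Buffer radius; wells exactly at the boundary are included.
    year : int, optional
        If given, restrict to wells active in that inventory year.

    Returns
    -------
    DataFrame
        The matching subset with an added ``distance_km`` column.  Empty
        subsets are valid and keep the full schema.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    sub = wells if year is None else wells[wells["year"] == year]
    if len(sub) == 0:
        out = sub.copy()
        out["distance_km"] = pd.Series(dtype=float)
        return out
    d = haversine_km(home, (sub["lat"].to_numpy(float), sub["lon"].to_numpy(float)))
    d = np.atleast_1d(d)
    out = sub.loc[d <= radius_km].copy()
    out["distance_km"] = d[d <= radius_km]
    return out


def cwd(home, wells: pd.DataFrame, radius_km: float = 5.0, year: int | None = None) -> float:
    """Cumulative well density: well count within the buffer / buffer area (wells/km²)."""
    n = len(wells_within_radius(home, wells, radius_km, year))
    return n / (np.pi * radius_km**2)


def idw_score(home, wells: pd.DataFrame, radius_km: float = 5.0, year: int | None = None) -> float:
    """Inverse-distance-weighted well score, ``sum(1/d_i)`` in km⁻¹.

    Wells nearer than :data:`IDW_FLOOR_KM` contribute ``1/IDW_FLOOR_KM``
    each; the inventory coordinates are not precise enough to resolve
    distances below 100 m and an unfloored score would be unbounded.
    """
    sub = wells_within_radius(home, wells, radius_km, year)
    if len(sub) == 0:
        return 0.0
    d = np.maximum(sub["distance_km"].to_numpy(float), IDW_FLOOR_KM)
    return float(np.sum(1.0 / d))


def buffer_clip_fraction(radius_km: float, boundary_distance_km: float) -> float:
    """Fraction of a circular buffer lying beyond a straight boundary line.

    ``boundary_distance_km`` is the perpendicular distance from the buffer
    centre (the home) to the boundary.  For a boundary at distance ``x < r``
    the clipped region is a circular segment of area
    ``r²·acos(x/r) − x·sqrt(r² − x²)``; the fraction is that area over
    ``π·r²``.  Returns 0 when the boundary does not intersect the buffer.
    """
    r, x = float(radius_km), float(boundary_distance_km)
    if r <= 0:
        raise ValueError("radius_km must be positive")
    if x < 0:
        raise ValueError("boundary distance must be non-negative")
    if x >= r:
        return 0.0
    seg = r * r * np.arccos(x / r) - x * np.sqrt(r * r - x * x)
    return float(seg / (np.pi * r * r))


def read_well_table(path) -> pd.DataFrame:
    """Read a well inventory CSV (columns :data:`WELL_COLUMNS`), validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table missing required columns: {missing}")
    _check_latlon(df["lat"].to_numpy(float), df["lon"].to_numpy(float))
    emis = df[["co_tpy", "nox_tpy", "pm25_tpy", "voc_tpy"]].to_numpy(float)
    if np.any(emis < 0):
        raise ValueError("emissions must be non-negative")
    return df
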