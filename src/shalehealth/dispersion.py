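"""Annual emission concentration (AEC) at a residence via a screening box model.

The AEC measure turns an annual well-emissions inventory into an estimated
pollutant concentration (µg/m³) at each home.  The chain is:

1. convert each well's reported tons/year (CO + NOx + PM2.5 + VOC) to a
   single grams/hour rate;
2. classify every hour of a weather year into a Pasquill–Gifford stability
   class from cloud cover, wind speed and time of day;
3. for a hypothetical *reference well* emitting 300 g/h, compute the hourly
   near-source concentration at receptor distances of 0.5, 1, 2, 3 and 5 km
   with a box-model dilution kernel, and take the 90th percentile of the
   8760-hour series per distance bin and directional quadrant;
4. scale each real well's contribution by its emission rate relative to
   300 g/h and the 90th-percentile value for its distance bin and quadrant,
   and sum contributions of all wells within 5 km of the home.

The box model treats emissions as diluted in a volume advected downwind;
concentration is source rate divided by wind speed times the box
cross-section.  The cross-section grows with downwind distance following the
Briggs open-country dispersion curves (constants in
:data:`BRIGGS_OPEN_COUNTRY`).  Plume direction is NOT modelled: every hour's
plume is assumed to impact the receptor (screening worst case), so the four
quadrants share one percentile series; the quadrant axis is kept in the
reference table for future wind-rose weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SHORT_TON_G = 907_184.74
METRIC_TON_G = 1_000_000.0
HOURS_PER_YEAR = 8760.0
REFERENCE_RATE_G_PER_H = 300.0

#: receptor distance bins (km) of the reference-well percentile table
DISTANCE_BINS_KM = (0.5, 1.0, 2.0, 3.0, 5.0)
QUADRANTS = ("NE", "SE", "SW", "NW")
STABILITY_CLASSES = ("A", "B", "C", "D", "E", "F")

#: wind-speed floor (m/s) for calm hours; avoids division by zero and is
#: standard screening practice
WIND_FLOOR_MS = 0.5

POLLUTANT_COLUMNS = ("co_tpy", "nox_tpy", "pm25_tpy", "voc_tpy")

# Briggs open-country sigma curves, sigma = a*x*(1 + b*x)**p with x the
# downwind distance in metres (valid ~100 m to 10 km).
BRIGGS_OPEN_COUNTRY = {
    #        sigma_y (a, b, p)          sigma_z (a, b, p)
    "A": ((0.22, 1e-4, -0.5), (0.20, 0.0, 0.0)),
    "B": ((0.16, 1e-4, -0.5), (0.12, 0.0, 0.0)),
    "C": ((0.11, 1e-4, -0.5), (0.08, 2e-4, -0.5)),
    "D": ((0.08, 1e-4, -0.5), (0.06, 1.5e-3, -0.5)),
    "E": ((0.06, 1e-4, -0.5), (0.03, 3e-4, -1.0)),
    "F": ((0.04, 1e-4, -0.5), (0.016, 3e-4, -1.0)),
}

__all__ = [
    "SHORT_TON_G",
    "METRIC_TON_G",
    "REFERENCE_RATE_G_PER_H",
    "DISTANCE_BINS_KM",
    "QUADRANTS",
    "STABILITY_CLASSES",
    "WIND_FLOOR_MS",
    "BRIGGS_OPEN_COUNTRY",
    "ReferenceP90Table",
    "tons_per_year_to_g_per_h",
    "stability_class",
    "classify_hours",
    "sigma_y_m",
    "sigma_z_m",
    "hourly_concentration",
    "build_reference_p90",
    "well_total_emission_rate",
    "distance_bin_km",
    "well_aec_contribution",
    "residence_aec",
]


def tons_per_year_to_g_per_h(rate_tpy, ton_g: float = SHORT_TON_G):
    """Convert an annual emission rate in tons/year to grams/hour.

    The default ton is the US short ton (907 184.74 g), the unit of the PA
    inventory; pass ``ton_g=METRIC_TON_G`` for metric tonnes.
    """
    rate = np.asarray(rate_tpy, dtype=float)
    if np.any(rate < 0):
        raise ValueError("emission rate must be non-negative")
    out = rate * ton_g / HOURS_PER_YEAR
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Pasquill–Gifford stability classification
# ---------------------------------------------------------------------------

# Wind-speed bin edges (m/s): <2, 2-3, 3-5, 5-6, >=6.  Rows are wind bins.
_DAY_TABLE = {
    # insolation: strong       moderate     slight
    0: ("A", "B", "B"),
    1: ("A", "B", "C"),
    2: ("B", "B", "C"),
    3: ("C", "C", "D"),
    4: ("D", "D", "D"),
}
_NIGHT_TABLE = {
    # sky:      clear  cloudy
    0: ("F", "E"),
    1: ("F", "E"),
    2: ("E", "D"),
    3: ("D", "D"),
    4: ("D", "D"),
}

DAY_START_HOUR = 7
DAY_END_HOUR = 18  # inclusive


def _wind_bin(u: np.ndarray) -> np.ndarray:
    return np.digitize(u, [2.0, 3.0, 5.0, 6.0])


def stability_class(hour_of_day: int, cloud_cover: float, wind_speed_ms: float) -> str:
    """Pasquill–Gifford stability class (A most unstable … F most stable).

    Decision table (a total function of the three inputs):

    * daytime = local hour in [7, 18]; insolation strong / moderate / slight
      for cloud cover < 1/3, [1/3, 2/3), ≥ 2/3;
    * night splits on cloud cover ≥ 4/8 (cloudy) vs < 4/8 (clear);
    * wind bins (m/s): <2, 2–3, 3–5, 5–6, ≥6; winds ≥ 6 m/s are neutral (D)
      under any sky.
    """
    return classify_hours(
        np.asarray([hour_of_day]), np.asarray([cloud_cover], float), np.asarray([wind_speed_ms], float)
    )[0]


def classify_hours(hour_of_day: np.ndarray, cloud_cover: np.ndarray, wind_speed_ms: np.ndarray) -> np.ndarray:
    """Vectorised :func:`stability_class` over hour arrays; returns an array of labels."""
    h = np.asarray(hour_of_day)
    cc = np.asarray(cloud_cover, dtype=float)
    u = np.asarray(wind_speed_ms, dtype=float)
    if np.any((cc < 0) | (cc > 1)):
        raise ValueError("cloud cover must lie in [0, 1]")
    if np.any(u < 0):
        raise ValueError("wind speed must be non-negative")
    wb = _wind_bin(u)
    day = (h >= DAY_START_HOUR) & (h <= DAY_END_HOUR)
    insol = np.digitize(cc, [1.0 / 3.0, 2.0 / 3.0])  # 0 strong, 1 moderate, 2 slight
    night_sky = (cc >= 0.5).astype(int)  # 0 clear, 1 cloudy
    out = np.empty(h.shape, dtype="<U1")
    for b in range(5):
        for i in range(3):
            out[day & (wb == b) & (insol == i)] = _DAY_TABLE[b][i]
        for s in range(2):
            out[~day & (wb == b) & (night_sky == s)] = _NIGHT_TABLE[b][s]
    return out


# ---------------------------------------------------------------------------
# Box-model dilution kernel
# ---------------------------------------------------------------------------


def _briggs(params, x_m):
    a, b, p = params
    if b == 0.0:
        return a * x_m
    return a * x_m * (1.0 + b * x_m) ** p


def sigma_y_m(cls: str, d_km):
    """Lateral dispersion length (m) at downwind distance ``d_km`` for a stability class."""
    return _briggs(BRIGGS_OPEN_COUNTRY[cls][0], np.asarray(d_km, dtype=float) * 1000.0)


def sigma_z_m(cls: str, d_km):
    """Vertical dispersion length (m) at downwind distance ``d_km`` for a stability class."""
    return _briggs(BRIGGS_OPEN_COUNTRY[cls][1], np.asarray(d_km, dtype=float) * 1000.0)


def hourly_concentration(q_g_per_h, u_ms, cls, d_km):
    """Hourly box-model concentration (µg/m³) at ``d_km`` downwind of a source.

    ``C = Q' / (u_eff · 2σy(d) · σz(d))`` with ``Q'`` the source rate in µg/s,
    ``u_eff = max(u, WIND_FLOOR_MS)``, and class-specific Briggs open-country
    dispersion lengths.  Accepts arrays for ``u_ms`` and ``cls`` (broadcast);
    strictly decreasing in distance and in effective wind speed.
    """
    q = np.asarray(q_g_per_h, dtype=float)
    d = np.asarray(d_km, dtype=float)
    if np.any(q < 0):
        raise ValueError("source rate must be non-negative")
    if np.any((d <= 0) | (d > 5.0)):
        raise ValueError("distance must lie in (0, 5] km")
    u_eff = np.maximum(np.asarray(u_ms, dtype=float), WIND_FLOOR_MS)
    cls_arr = np.asarray(cls)
    q_ug_s = q * 1e6 / 3600.0
    if cls_arr.ndim == 0:
        denom = u_eff * 2.0 * sigma_y_m(str(cls_arr), d) * sigma_z_m(str(cls_arr), d)
        out = q_ug_s / denom
    else:
        sy = np.empty(cls_arr.shape)
        sz = np.empty(cls_arr.shape)
        for c in STABILITY_CLASSES:
            m = cls_arr == c
            if np.any(m):
                sy[m] = sigma_y_m(c, d)
                sz[m] = sigma_z_m(c, d)
        out = q_ug_s / (u_eff * 2.0 * sy * sz)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class ReferenceP90Table:
    """90th-percentile reference-well concentrations by distance bin and quadrant.

    ``values[(d_km, quadrant)]`` is the 90th percentile (linear-interpolation
    definition) of the hourly µg/m³ series produced by a
    :data:`REFERENCE_RATE_G_PER_H` source over one weather year.
    """

    values: dict = field(default_factory=dict)
    reference_rate: float = REFERENCE_RATE_G_PER_H
    year: int | None = None

    def __getitem__(self, key):
        return self.values[key]

    def lookup(self, d_km: float, quadrant: str) -> float:
        return self.values[(distance_bin_km(d_km), quadrant)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"distance_km": d, "quadrant": q, "p90_ugm3": self.values[(d, q)], "year": self.year}
            for d in DISTANCE_BINS_KM
            for q in QUADRANTS
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceP90Table":
        year = int(df["year"].iloc[0]) if "year" in df.columns and df["year"].notna().any() else None
        values = {
            (float(r["distance_km"]), str(r["quadrant"])): float(r["p90_ugm3"]) for _, r in df.iterrows()
        }
        return cls(values=values, year=year)


def build_reference_p90(weather: pd.DataFrame, year: int | None = None) -> ReferenceP90Table:
    """Reference-well 90th-percentile concentration table from an hourly weather year.

    ``weather`` needs columns ``timestamp``, ``cloud_cover`` and
    ``wind_speed_ms``.  Each hour is stability-classified, the 300 g/h hourly
    concentration evaluated at each distance bin, and the 90th percentile
    taken per bin.  All four quadrants receive identical values because the
    plume is assumed to impact the receptor every hour.
    """
    if len(weather) == 0:
        raise ValueError("weather table is empty")
    ts = pd.to_datetime(weather["timestamp"])
    hours = ts.dt.hour.to_numpy()
    cc = weather["cloud_cover"].to_numpy(float)
    u = weather["wind_speed_ms"].to_numpy(float)
    cls = classify_hours(hours, cc, u)
    values: dict = {}
    for d in DISTANCE_BINS_KM:
        series = hourly_concentration(REFERENCE_RATE_G_PER_H, u, cls, d)
        p90 = float(np.percentile(series, 90.0))  # linear interpolation between order stats
        for q in QUADRANTS:
            values[(d, q)] = p90
    return ReferenceP90Table(values=values, year=year)


# ---------------------------------------------------------------------------
# Per-well scaling and aggregation
# ---------------------------------------------------------------------------


def well_total_emission_rate(well, ton_g: float = SHORT_TON_G) -> float:
    """Total CO + NOx + PM2.5 + VOC emission rate of a well in g/h.

    ``well`` is a mapping/Series with the tons/year columns of
    :data:`POLLUTANT_COLUMNS`.  Other columns (e.g. methane or CO2, which the
    inventory also reports but which lack health effects at expected exposure
    levels) are ignored.
    """
    total_tpy = sum(float(well[c]) for c in POLLUTANT_COLUMNS)
    return tons_per_year_to_g_per_h(total_tpy, ton_g=ton_g)


def distance_bin_km(d_km: float) -> float:
    """Map a well distance to the nearest reference bin; distances < 0.5 km use 0.5 km."""
    bins = np.asarray(DISTANCE_BINS_KM)
    return float(bins[np.argmin(np.abs(bins - float(d_km)))])


def well_aec_contribution(well, home, p90: ReferenceP90Table, ton_g: float = SHORT_TON_G) -> float:
    """One well's µg/m³ contribution at ``home``: rate × P90[bin, quadrant] / 300 g/h.

    Raises ``ValueError`` if the well lies beyond 5 km.
    """
    from . import geo

    d = geo.haversine_km(home, (float(well["lat"]), float(well["lon"])))
    if d > 5.0:
        raise ValueError(f"well at {d:.2f} km is beyond the 5 km model range")
    if d == 0.0:
        quad = "NE"  # co-located well: bearing undefined, bin is 0.5 km either way
    else:
        quad = geo.quadrant_of(home, (float(well["lat"]), float(well["lon"])))
    rate = well_total_emission_rate(well, ton_g=ton_g)
    return rate * p90.lookup(d, quad) / p90.reference_rate


def residence_aec(
    home,
    wells: pd.DataFrame,
    p90: ReferenceP90Table,
    year: int | None = None,
    ton_g: float = SHORT_TON_G,
) -> float:
    """Annual emission concentration at a residence: sum of all well contributions within 5 km.

    Vectorised, but numerically identical to summing
    :func:`well_aec_contribution` over the wells within range.
    """
    from . import geo

    sub = geo.wells_within_radius(home, wells, 5.0, year)
    if len(sub) == 0:
        return 0.0
    d = sub["distance_km"].to_numpy(float)
    rates = tons_per_year_to_g_per_h(
        sub[list(POLLUTANT_COLUMNS)].to_numpy(float).sum(axis=1), ton_g=ton_g
    )
    bearings = np.atleast_1d(
        geo.initial_bearing_deg(home, (sub["lat"].to_numpy(float), sub["lon"].to_numpy(float)))
    )
    quads = np.asarray(QUADRANTS)[(bearings // 90.0).astype(int) % 4]
    quads[d == 0.0] = "NE"  # co-located well: bearing undefined, bin is 0.5 km either way
    bins = np.asarray(DISTANCE_BINS_KM)
    bin_idx = np.argmin(np.abs(bins[None, :] - d[:, None]), axis=1)
    p90_vals = np.array([p90.values[(float(bins[b]), q)] for b, q in zip(bin_idx, quads)])
    return float(np.sum(rates * p90_vals / p90.reference_rate))
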