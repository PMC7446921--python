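import numpy as np
import pandas as pd
import pytest

from shalehealth.geo import EARTH_RADIUS_KM


def well_row(well_id, lat, lon, year=2016, co=1.0, nox=1.0, pm25=1.0, voc=1.0):
    return {
        "well_id": well_id,
        "lat": lat,
        "lon": lon,
        "year": year,
        "co_tpy": co,
        "nox_tpy": nox,
        "pm25_tpy": pm25,
        "voc_tpy": voc,
    }


def wells_at_distances(home, distances_km, bearing="north", **kw):
    """Wells placed due north (meridian arc) at exact great-circle distances."""
    lat0, lon0 = home
    rows = []
    for i, d in enumerate(distances_km):
        dlat = d / EARTH_RADIUS_KM * 180.0 / np.pi
        rows.append(well_row(f"T{i}", lat0 + dlat, lon0, **kw))
    return pd.DataFrame(rows)


@pytest.fixture
def home():
    return (40.0, -80.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_wells(rng):
    n = 50
    return pd.DataFrame(
        [
            well_row(
                f"R{i}",
                40.0 + rng.uniform(-0.1, 0.1),
                -80.0 + rng.uniform(-0.1, 0.1),
                co=rng.uniform(0, 5),
                nox=rng.uniform(0, 5),
                pm25=rng.uniform(0, 1),
                voc=rng.uniform(0, 5),
            )
            for i in range(n)
        ]
    )
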