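"""Synthetic wells, weather and respondents with the structure the analysis assumes.

Nothing in the real study is distributable — health records are confidential
and the well inventory lives behind a state portal — so this module
generates all three inputs with the statistical features the downstream
stages rely on:

* **wells**: uniformly placed in a lat/lon bounding box, with log-normal
  per-pollutant annual emissions (CO, NOx, PM2.5, VOC) whose total has a
  configurable mean;
* **weather**: a complete hourly year of cloud cover in [0, 1] and
  non-negative wind speed, both temporally autocorrelated, wind with a
  diurnal cycle peaking mid-afternoon;
* **respondents**: homes in the box, adult ages, sex / smoker / water-source
  demographics, and a binary symptom matrix whose row totals follow a
  Poisson log-linear dose–response on the respondent's true
  inverse-distance-weighted (IDW) exposure.  A configurable subset of
  symptoms is *gradient-responsive*: above an exposure threshold their
  reporting odds are multiplied, which is exactly the step structure the
  TITAN stage is designed to detect.

All randomness flows from one seed through a splittable ``SeedSequence`` so
the three generators are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .cohort import SYMPTOM_PREFIX, SymptomDictionary, CATEGORIES
from .geo import WELL_COLUMNS

#: pollutant shares of a well's mean total annual emissions
POLLUTANT_SHARES = {"co_tpy": 0.40, "nox_tpy": 0.30, "pm25_tpy": 0.05, "voc_tpy": 0.25}

#: log-scale sd of each pollutant's log-normal emission distribution
EMISSION_LOG_SD = 1.0

__all__ = [
    "SimulationConfig",
    "generate_wells",
    "generate_weather",
    "generate_respondents",
    "generate_assessment_records",
    "symptom_names",
    "symptom_dictionary_for",
    "write_csv",
    "config_to_yaml",
    "config_from_yaml",
]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the design of the motivating study: 104 adult
    respondents assessed in one year in a ~1°×1° patch of southwest
    Pennsylvania, a mean of 7 reported symptoms at zero (standardised)
    exposure, 59% female with a +0.49 log-rate effect, 40% ever-smokers
    with +0.52, smoker status missing for 25%, and a 5 km exposure buffer.
    """

    n_wells: int = 400
    n_respondents: int = 104
    bbox: tuple = (39.7, 40.7, -80.5, -79.5)  # (lat_min, lat_max, lon_min, lon_max)
    year: int = 2016
    emission_scale: float = 50.0  # mean total tons/year per well
    dose_response_beta: float = 0.5  # log-rate per SD of true exposure
    baseline_rate: float = 7.0  # mean symptom count at zero standardised exposure
    n_symptoms: int = 40
    seed: int = 0
    radius_km: float = 5.0
    # demographics
    p_female: float = 0.59
    p_ever_smoker: float = 0.40
    p_municipal_water: float = 1.0 / 3.0
    female_effect: float = 0.49  # log-rate effects sized to match typical cohort estimates
    smoker_effect: float = 0.52
    smoker_missing_fraction: float = 0.25
    age_range: tuple = (18, 90)
    # gradient-responsive symptom structure (the TITAN signal)
    # A responsive symptom's sampling weight is multiplied by the affinity
    # above the exposure threshold and divided by it below, making its
    # occurrence a crisp step on the gradient.  The default is sized so the
    # step is reliably detectable by a permutation test at n ~ 100: upper
    # occurrence rates reach ~0.5-0.7 while lower rates stay near zero.
    n_responsive_symptoms: int = 10
    responsive_affinity: float = 25.0
    # Exposure quantile where responsiveness switches on.  An upper quartile
    # keeps the suppressed-group (all picks are reallocated towards
    # responsive symptoms above the threshold, so the other symptoms dip
    # there) small enough that non-responsive symptoms stay effectively null.
    threshold_quantile: float = 0.75
    # The dose entering the log-linear rate is the standardised exposure
    # winsorised at +/- this many SDs: inverse-distance exposures are heavy
    # tailed (a home right on a well pad sits many SDs out), and an
    # unsaturated log-linear response would assign such homes astronomical
    # expected counts that the symptom dictionary cannot express.
    dose_winsor_sd: float = 3.0

    def validate(self) -> None:
        lat0, lat1, lon0, lon1 = self.bbox
        if not (lat1 > lat0 and lon1 > lon0):
            raise ValueError("bbox must span > 0 degrees on both axes")
        if self.n_wells < 0 or self.n_respondents < 0:
            raise ValueError("counts must be non-negative")
        if self.emission_scale <= 0:
            raise ValueError("emission_scale must be positive")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.n_symptoms < 1:
            raise ValueError("n_symptoms must be >= 1")
        if not (0 <= self.smoker_missing_fraction <= 1):
            raise ValueError("smoker_missing_fraction must lie in [0, 1]")
        a0, a1 = self.age_range
        if not (0 <= a0 < a1):
            raise ValueError("invalid age range")
        if not (0 <= self.n_responsive_symptoms <= self.n_symptoms):
            raise ValueError("n_responsive_symptoms must lie in [0, n_symptoms]")
        for p in (self.p_female, self.p_ever_smoker, self.p_municipal_water):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


def _streams(config: SimulationConfig):
    return np.random.SeedSequence(config.seed).spawn(3)


def symptom_names(n_symptoms: int) -> list[str]:
    """Symptom names for a synthetic cohort: the shipped dictionary's names first,
    generic ``symptom_##`` beyond."""
    base = list(SymptomDictionary.default().mapping)
    if n_symptoms <= len(base):
        return base[:n_symptoms]
    extra = [f"symptom_{i:02d}" for i in range(n_symptoms - len(base))]
    return base + extra


def symptom_dictionary_for(n_symptoms: int) -> SymptomDictionary:
    """Dictionary covering a synthetic cohort's symptoms; generic extras cycle
    through the nine categories (synthetic placeholders, not clinical claims)."""
    base = SymptomDictionary.default().mapping
    names = symptom_names(n_symptoms)
    mapping = {s: base.get(s, CATEGORIES[i % len(CATEGORIES)]) for i, s in enumerate(names)}
    return SymptomDictionary(mapping)


def generate_wells(config: SimulationConfig) -> pd.DataFrame:
    """Uniformly placed wells with log-normal per-pollutant annual emissions.

    Each pollutant's tons/year is log-normal with mean ``share *
    emission_scale`` (shares in :data:`POLLUTANT_SHARES`) and log-sd
    :data:`EMISSION_LOG_SD`, so the expected total per well equals
    ``emission_scale``.
    """
    config.validate()
    rng = np.random.default_rng(_streams(config)[0])
    n = config.n_wells
    lat0, lat1, lon0, lon1 = config.bbox
    df = pd.DataFrame(
        {
            "well_id": [f"W{i:05d}" for i in range(n)],
            "lat": rng.uniform(lat0, lat1, size=n),
            "lon": rng.uniform(lon0, lon1, size=n),
            "year": np.full(n, config.year, dtype=int),
        }
    )
    for col, share in POLLUTANT_SHARES.items():
        mean = share * config.emission_scale
        mu = np.log(mean) - 0.5 * EMISSION_LOG_SD**2
        df[col] = rng.lognormal(mu, EMISSION_LOG_SD, size=n)
    return df[list(WELL_COLUMNS)]


def generate_weather(year: int, seed=None) -> pd.DataFrame:
    """One complete hourly weather year (8760 rows, 8784 in leap years).

    Cloud cover is a logistic-mapped AR(1) latent (smooth, in [0, 1]); wind
    speed is a diurnal base (peak ~15:00 local, mean ≈ 3 m/s) modulated by a
    log-scale AR(1), hence strictly positive.
    """
    if year < 1:
        raise ValueError("year must be a positive calendar year")
    rng = np.random.default_rng(seed)
    ts = pd.date_range(f"{year}-01-01", f"{year}-12-31 23:00", freq="h")
    n = len(ts)
    rho = 0.97

    def ar1(scale):
        x = np.empty(n)
        x[0] = rng.normal(0, scale)
        innov = rng.normal(0, scale * np.sqrt(1 - rho**2), size=n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + innov[t]
        return x

    cloud = 1.0 / (1.0 + np.exp(-1.5 * ar1(1.0)))
    hours = ts.hour.to_numpy()
    diurnal = 3.0 + 1.5 * np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)
    wind = diurnal * np.exp(0.4 * ar1(1.0))
    return pd.DataFrame({"timestamp": ts, "cloud_cover": cloud, "wind_speed_ms": wind})


def _true_exposures(config: SimulationConfig, wells: pd.DataFrame, lat, lon) -> np.ndarray:
    """Vectorised IDW scores; identical to :func:`shalehealth.geo.idw_score` per home."""
    from .geo import IDW_FLOOR_KM, pairwise_distances_km

    sub = wells[wells["year"] == config.year]
    if len(sub) == 0:
        return np.zeros(len(np.atleast_1d(lat)))
    D = pairwise_distances_km((lat, lon), (sub["lat"].to_numpy(), sub["lon"].to_numpy()))
    in_range = D <= config.radius_km
    return np.sum(np.where(in_range, 1.0 / np.maximum(D, IDW_FLOOR_KM), 0.0), axis=1)


def generate_respondents(config: SimulationConfig, wells: pd.DataFrame) -> pd.DataFrame:
    """Synthetic cohort with a Poisson log-linear dose–response on IDW exposure.

    The expected symptom count of respondent *i* is

        lambda_i = baseline_rate * exp(beta * z_i + a_f * F_i + a_s * S_i) / c

    with ``z_i`` the cohort-standardised true IDW exposure (winsorised at
    ``dose_winsor_sd`` SDs, see :class:`SimulationConfig`), ``F/S`` the
    female and ever-smoker indicators, and ``c`` the analytic demographic
    correction ``E[exp(a_f F + a_s S)]`` so that the cohort mean at ``beta=0``
    equals ``baseline_rate`` exactly in expectation.  The Poisson draw is
    capped at ``n_symptoms`` (binary coding cannot exceed the dictionary) and
    distributed as 1s over symptom columns by weighted sampling without
    replacement; gradient-responsive symptoms get ``responsive_affinity``
    times the weight for respondents above the ``threshold_quantile`` of
    exposure.

    The returned frame carries the truth needed by tests: a
    ``true_exposure`` column and ``attrs['responsive_symptoms']`` /
    ``attrs['exposure_threshold']``.
    """
    config.validate()
    if config.dose_response_beta != 0 and len(wells) == 0:
        raise ValueError("non-zero dose_response_beta requires a non-empty well table")
    rng = np.random.default_rng(_streams(config)[2])
    n = config.n_respondents
    lat0, lat1, lon0, lon1 = config.bbox
    lat = rng.uniform(lat0, lat1, size=n)
    lon = rng.uniform(lon0, lon1, size=n)
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    female = rng.random(n) < config.p_female
    ever = rng.random(n) < config.p_ever_smoker
    smoker_missing = rng.random(n) < config.smoker_missing_fraction
    municipal = rng.random(n) < config.p_municipal_water

    exposure = (
        _true_exposures(config, wells, lat, lon) if len(wells) else np.zeros(n)
    )
    sd = exposure.std()
    z = (exposure - exposure.mean()) / sd if sd > 0 else np.zeros(n)
    z = np.clip(z, -config.dose_winsor_sd, config.dose_winsor_sd)

    # analytic demographic mean-correction (see docstring)
    corr = (1 - config.p_female + config.p_female * np.exp(config.female_effect)) * (
        1 - config.p_ever_smoker + config.p_ever_smoker * np.exp(config.smoker_effect)
    )
    lam = (
        config.baseline_rate
        * np.exp(
            config.dose_response_beta * z
            + config.female_effect * female
            + config.smoker_effect * ever
        )
        / corr
    )
    counts = np.minimum(rng.poisson(lam), config.n_symptoms)

    names = symptom_names(config.n_symptoms)
    responsive = np.sort(
        rng.choice(config.n_symptoms, size=config.n_responsive_symptoms, replace=False)
    )
    threshold = float(np.quantile(exposure, config.threshold_quantile)) if n else 0.0
    base_w = 1.0 / np.sqrt(1.0 + np.arange(config.n_symptoms))  # heterogeneous popularity
    sym = np.zeros((n, config.n_symptoms), dtype=int)
    for i in range(n):
        if counts[i] == 0:
            continue
        w = base_w.copy()
        # responsive symptoms concentrate above the threshold: boosted there,
        # suppressed below, so their occurrence is a crisp step on the gradient
        if exposure[i] > threshold:
            w[responsive] *= config.responsive_affinity
        else:
            w[responsive] /= config.responsive_affinity
        picks = rng.choice(config.n_symptoms, size=counts[i], replace=False, p=w / w.sum())
        sym[i, picks] = 1

    df = pd.DataFrame(
        {
            "id": [f"R{i:04d}" for i in range(n)],
            "lat": lat,
            "lon": lon,
            "year": np.full(n, config.year, dtype=int),
            "age": age,
            "sex": np.where(female, "female", "male"),
            "smoker": np.where(smoker_missing, "missing", np.where(ever, "ever", "never")),
            "water_source": np.where(municipal, "municipal", "well_or_spring"),
            "true_exposure": exposure,
            "true_dose_z": z,  # the winsorised standardised dose actually applied
        }
    )
    sym_df = pd.DataFrame(sym, columns=[SYMPTOM_PREFIX + name for name in names])
    df = pd.concat([df, sym_df], axis=1)
    df.attrs["responsive_symptoms"] = [names[j] for j in responsive]
    df.attrs["exposure_threshold"] = threshold
    return df


def generate_assessment_records(
    config: SimulationConfig,
    wells: pd.DataFrame,
    n_stage1_excluded: int = 17,
    n_stage2_excluded: int = 14,
) -> pd.DataFrame:
    """Raw assessment table including records destined for exclusion.

    Appends ``n_stage1_excluded`` records carrying one review-stage flag each
    (minor / industry worker / out of state / incomplete) and
    ``n_stage2_excluded`` records without residence coordinates, so the
    two-stage exclusion flow can be exercised end to end.  The analysable
    core is exactly ``generate_respondents(config, wells)``.
    """
    core = generate_respondents(config, wells)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xF1A6)).generate_state(1)[0])
    from .cohort import STAGE1_FLAGS

    for f in (*STAGE1_FLAGS, "flag_no_coordinates"):
        core[f] = False
    extras = []
    for j in range(n_stage1_excluded + n_stage2_excluded):
        row = core.iloc[int(rng.integers(len(core)))].copy()
        row["id"] = f"X{j:04d}"
        for f in (*STAGE1_FLAGS, "flag_no_coordinates"):
            row[f] = False
        if j < n_stage1_excluded:
            row[STAGE1_FLAGS[int(rng.integers(len(STAGE1_FLAGS)))]] = True
        else:
            row["flag_no_coordinates"] = True
            row["lat"] = np.nan
            row["lon"] = np.nan
        extras.append(row)
    out = pd.concat([core, pd.DataFrame(extras)], ignore_index=True)
    return out.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def write_csv(df: pd.DataFrame, path) -> None:
    """Write any generated table as CSV with its documented header."""
    df.to_csv(path, index=False)


def config_to_yaml(config: SimulationConfig, path) -> None:
    d = asdict(config)
    d["bbox"] = list(d["bbox"])
    d["age_range"] = list(d["age_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "bbox" in d:
        d["bbox"] = tuple(d["bbox"])
    if "age_range" in d:
        d["age_range"] = tuple(d["age_range"])
    return SimulationConfig(**d)
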