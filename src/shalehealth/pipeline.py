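"""End-to-end orchestration: inputs → exposures → GLM selection → TITAN → artifacts.

:func:`run_pipeline` wires the stages together for either simulated or
file-based inputs and writes every numeric result as CSV/JSON (figures are
optional extras), plus a manifest with the seed and package versions so a
rerun is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, dispersion, geo, glm, simulate, titan

logger = logging.getLogger("shalehealth")

EXPOSURES = ("cwd", "idw", "aec")

__all__ = ["PipelineConfig", "run_pipeline", "compute_exposures", "correlate_exposures", "EXPOSURES"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run (simulation mode or file inputs)."""

    outdir: str = "results"
    seed: int = 0
    simulate: bool = True
    sim: simulate.SimulationConfig | None = None
    wells_path: str | None = None
    respondents_path: str | None = None
    weather_path: str | None = None
    radius_km: float = 5.0
    exposures: tuple = EXPOSURES
    glm_candidates: tuple = glm.DEMOGRAPHIC_CANDIDATES
    titan_min_frequency: int = 5
    titan_min_split: int = 5
    titan_n_perm: int = 250
    titan_n_boot: int = 500
    make_figures: bool = False

    def validate(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")
        if not self.exposures:
            raise ValueError("select at least one exposure")
        unknown = [e for e in self.exposures if e not in EXPOSURES]
        if unknown:
            raise ValueError(f"unknown exposures: {unknown}")
        if not self.simulate:
            for p, what in (
                (self.wells_path, "wells"),
                (self.respondents_path, "respondents"),
                (self.weather_path, "weather"),
            ):
                if p is None:
                    raise ValueError(f"{what} path required when not simulating")


def compute_exposures(
    respondents: pd.DataFrame,
    wells: pd.DataFrame,
    weather: pd.DataFrame,
    radius_km: float = 5.0,
    match_year: bool = True,
) -> pd.DataFrame:
    """Per-respondent CWD, IDW and AEC values.

    The AEC reference percentile table is built once from the supplied
    hourly weather year and applied to every respondent (single-station
    design; if respondents span assessment years, supply the matching
    weather year per run).
    """
    p90 = dispersion.build_reference_p90(weather)
    D = geo.pairwise_distances_km(
        (respondents["lat"].to_numpy(float), respondents["lon"].to_numpy(float)),
        (wells["lat"].to_numpy(float), wells["lon"].to_numpy(float)),
    )
    if match_year:
        year_ok = (
            respondents["year"].to_numpy(int)[:, None] == wells["year"].to_numpy(int)[None, :]
        )
    else:
        year_ok = np.ones_like(D, dtype=bool)
    in_range = (D <= radius_km) & year_ok
    cwd_vals = in_range.sum(axis=1) / (np.pi * radius_km**2)
    idw_vals = np.sum(
        np.where(in_range, 1.0 / np.maximum(D, geo.IDW_FLOOR_KM), 0.0), axis=1
    )
    aec_vals = [
        dispersion.residence_aec(
            (float(r["lat"]), float(r["lon"])),
            wells,
            p90,
            int(r["year"]) if match_year else None,
        )
        for _, r in respondents.iterrows()
    ]
    return pd.DataFrame(
        {
            "id": respondents["id"].to_numpy(),
            "cwd": cwd_vals,
            "idw": idw_vals,
            "aec": aec_vals,
            "radius_km": radius_km,
        }
    )


def correlate_exposures(exposures: pd.DataFrame, columns=EXPOSURES) -> pd.DataFrame:
    """Pairwise Pearson correlations among the exposure measures.

    Requires ≥ 3 respondents; zero-variance columns produce NaN entries and
    a logged warning rather than an error.
    """
    cols = [c for c in columns if c in exposures.columns]
    if len(exposures) < 3:
        raise ValueError("need at least 3 respondents to correlate exposures")
    for c in cols:
        if exposures[c].std() == 0:
            logger.warning("exposure %r has zero variance; correlations undefined", c)
    return exposures[cols].corr(method="pearson")


def _fig_path(outdir: Path, name: str) -> Path:
    return outdir / f"{name}.svg"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to the outdir).

    Outputs (all CSV/JSON): cohort audit, exposure table, exposure
    correlations, symptom frequency table, per-exposure ranked GLM model
    tables and best-fit reports, per-exposure TITAN tables and filtered
    reports, and ``manifest.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    if config.simulate:
        sim = config.sim or simulate.SimulationConfig(seed=config.seed)
        wells = simulate.generate_wells(sim)
        weather = simulate.generate_weather(sim.year, seed=np.random.SeedSequence((sim.seed, 1)))
        records = simulate.generate_assessment_records(sim, wells)
    else:
        wells = geo.read_well_table(config.wells_path)
        records = pd.read_csv(config.respondents_path)
        weather = pd.read_csv(config.weather_path)
        required = {"timestamp", "cloud_cover", "wind_speed_ms"}
        missing = required - set(weather.columns)
        if missing:
            raise ValueError(f"weather table missing columns: {sorted(missing)}")

    # ---- cohort -----------------------------------------------------------
    stage1, audit1 = cohort.apply_stage1_exclusions(records)
    analysed, audit2 = cohort.apply_stage2_exclusions(stage1)
    audit = {"stage1": audit1.to_dict(), "stage2": audit2.to_dict(), "n_analysed": len(analysed)}
    (outdir / "cohort_audit.json").write_text(json.dumps(audit, indent=2))
    if len(analysed) == 0:
        raise ValueError("no respondents remain after exclusions")

    freq = cohort.frequency_table(analysed)
    freq.to_csv(outdir / "frequency_table.csv", index=False)

    # ---- exposures --------------------------------------------------------
    exposures = compute_exposures(analysed, wells, weather, config.radius_km)
    exposures.to_csv(outdir / "exposures.csv", index=False)
    corr = correlate_exposures(exposures, config.exposures)
    corr.to_csv(outdir / "exposure_correlations.csv")

    data = analysed.merge(exposures, on="id")
    data["symptom_total"] = data[cohort.symptom_columns(data)].sum(axis=1)

    # ---- GLM and TITAN per exposure --------------------------------------
    manifest: dict = {
        "seed": config.seed,
        "radius_km": config.radius_km,
        "audit": audit,
        "exposures": {},
        "versions": _versions(),
    }
    sym_cols = cohort.symptom_columns(analysed)
    symptoms = analysed[sym_cols].rename(columns=lambda c: c[len(cohort.SYMPTOM_PREFIX):])
    ss = np.random.SeedSequence((config.seed, 2)).spawn(len(config.exposures))
    for k, exp in enumerate(config.exposures):
        block: dict = {}
        sel = glm.PoissonExposureModel(data, exp).select_demographics(config.glm_candidates)
        tab = sel.table.copy()
        tab["demographics"] = tab["demographics"].map(lambda t: "+".join(t))
        tab["terms"] = tab["terms"].map(lambda t: "+".join(t))
        tab.to_csv(outdir / f"glm_{exp}_models.csv", index=False)
        best = glm.PoissonExposureModel(data, exp, sel.best_terms).fit()
        (outdir / f"glm_{exp}_fit.json").write_text(json.dumps(best.to_dict(), indent=2))
        block["glm_best_demographics"] = list(sel.best_terms)
        block["glm_best_aicc"] = best.aicc

        model = titan.TitanModel(
            symptoms,
            data[exp].to_numpy(float),
            min_frequency=config.titan_min_frequency,
            min_split=config.titan_min_split,
            gradient_name=exp,
        )
        res = model.fit(
            n_perm=config.titan_n_perm,
            n_boot=config.titan_n_boot,
            seed=ss[k],
        )
        res.to_csv(outdir / f"titan_{exp}.csv")
        report = res.report_filter()
        report.to_csv(outdir / f"titan_{exp}_report.csv", index=False)
        block["titan_n_analysed"] = len(res.table)
        block["titan_n_significant"] = int(res.table["significant"].sum())
        block["titan_n_reported"] = len(report)
        if config.make_figures and len(report):
            ax = res.plot_spectrum()
            ax.figure.savefig(_fig_path(outdir, f"titan_{exp}_spectrum"), bbox_inches="tight")
        manifest["exposures"][exp] = block

    manifest["n_rows"] = {
        "wells": len(wells),
        "records_in": len(records),
        "analysed": len(analysed),
        "exposure_table": len(exposures),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _versions() -> dict:
    import statsmodels

    from . import __version__

    return {
        "shalehealth": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
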