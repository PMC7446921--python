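"""Poisson regression of symptom totals on exposure, with AICc model selection.

The response is each respondent's total symptom count, modelled as Poisson
with a log link.  One exposure measure (CWD, IDW or AEC) is always present;
demographic covariates (age, sex, smoker status, water source) are optional
and selected by exhaustively fitting every demographic subset and ranking by
AICc, the small-sample-corrected Akaike information criterion

    AICc = AIC + 2k(k+1)/(n - k - 1).

Main entry points
-----------------
:class:`PoissonExposureModel`
    statsmodels-style model object; ``.fit()`` returns
    :class:`PoissonExposureResults`, ``.select_demographics()`` runs the
    exhaustive subset search.
:func:`fit_poisson`
    plain function over a count vector and design matrix.
:func:`spatial_scale_selection`
    fits the same model at several buffer radii and picks the radius with
    the lowest AIC.

Rows with missing values in any *included* covariate are dropped
(complete-case per candidate model).  Categorical covariates are dummy
coded; reference levels default to male / never-smoker / municipal water and
are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEMOGRAPHIC_CANDIDATES = ("age", "sex", "smoker", "water_source")

_DEFAULT_REFERENCES = {"sex": "male", "smoker": "never", "water_source": "municipal"}

__all__ = [
    "DEMOGRAPHIC_CANDIDATES",
    "GlmFit",
    "PoissonExposureModel",
    "PoissonExposureResults",
    "SelectionResults",
    "fit_poisson",
    "aicc",
    "build_design",
    "exhaustive_selection",
    "spatial_scale_selection",
]


def aicc(aic: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``AIC + 2k(k+1)/(n-k-1)``; requires ``n > k+1``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class GlmFit:
    """Container for one fitted Poisson GLM.

    ``coefficients`` maps each term to ``(estimate, std_error, z, p)``; the
    information criteria use ``AIC = -2*llf + 2k``.
    """

    coefficients: dict
    log_likelihood: float
    aic: float
    aicc: float
    n_used: int
    residual_df: int
    terms: tuple = ()
    converged: bool = True

    @property
    def k(self) -> int:
        return len(self.coefficients)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "estimate": e, "std_error": se, "z": z, "p_value": p}
            for t, (e, se, z, p) in self.coefficients.items()
        ]
        return pd.DataFrame(rows)


def fit_poisson(y, X: pd.DataFrame) -> GlmFit:
    """Maximum-likelihood Poisson GLM with log link (IRLS via statsmodels).

    ``X`` must be a DataFrame including any intercept column.  Raises on
    constant-zero columns, singular designs and non-convergence.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    Xv = X.to_numpy(dtype=float)
    if Xv.shape[0] != y.shape[0]:
        raise ValueError("y and X have different lengths")
    zero_cols = [c for c, col in zip(X.columns, Xv.T) if np.all(col == 0)]
    if zero_cols:
        raise ValueError(f"constant-zero design columns: {zero_cols}")
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    model = sm.GLM(y, Xv, family=sm.families.Poisson())
    res = model.fit(maxiter=100)
    if not res.converged:
        raise RuntimeError(f"Poisson IRLS did not converge in {res.fit_history['iteration']} iterations")
    k = Xv.shape[1]
    n = len(y)
    coeffs = {
        name: (float(res.params[i]), float(res.bse[i]), float(res.tvalues[i]), float(res.pvalues[i]))
        for i, name in enumerate(X.columns)
    }
    aic_val = -2.0 * float(res.llf) + 2.0 * k
    return GlmFit(
        coefficients=coeffs,
        log_likelihood=float(res.llf),
        aic=aic_val,
        aicc=aicc(aic_val, k, n),
        n_used=n,
        residual_df=n - k,
        terms=tuple(X.columns),
    )


def build_design(
    data: pd.DataFrame,
    exposure: str,
    demographics=(),
    references: dict | None = None,
):
    """Design matrix for one candidate model: intercept + exposure + dummies.

    Returns ``(y, X, index_used)`` after complete-case filtering on the
    response, the exposure and the *included* demographics only.
    """
    refs = dict(_DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    needed = ["symptom_total", exposure, *demographics]
    sub = data[needed].copy()
    # treat explicit "missing" markers as NaN for categorical covariates
    for col in demographics:
        if col in refs:
            sub[col] = sub[col].replace("missing", np.nan)
    sub = sub.dropna()
    X = pd.DataFrame(index=sub.index)
    X["intercept"] = 1.0
    X[exposure] = sub[exposure].astype(float)
    for col in demographics:
        if col in refs:
            levels = [lv for lv in pd.unique(sub[col]) if lv != refs[col]]
            for lv in sorted(map(str, levels)):
                X[f"{col}[{lv}]"] = (sub[col].astype(str) == lv).astype(float)
        else:
            X[col] = sub[col].astype(float)
    return sub["symptom_total"].to_numpy(float), X, sub.index


@dataclass
class SelectionResults:
    """Ranked table of all candidate models from an exhaustive subset search."""

    table: pd.DataFrame
    fits: dict = field(repr=False, default_factory=dict)

    @property
    def best_terms(self) -> tuple:
        return self.table.iloc[0]["demographics"]

    @property
    def best_fit(self) -> GlmFit:
        return self.fits[self.best_terms]

    def summary(self) -> str:
        lines = ["Exhaustive Poisson model selection (ranked by AICc)", "-" * 52]
        for _, r in self.table.iterrows():
            demo = ", ".join(r["demographics"]) or "(exposure only)"
            lines.append(f"{r['rank']:>4}  AICc={r['aicc']:10.3f}  AIC={r['aic']:10.3f}  k={r['k']}  {demo}")
        return "\n".join(lines)


def exhaustive_selection(
    data: pd.DataFrame,
    exposure: str,
    candidates=DEMOGRAPHIC_CANDIDATES,
    references: dict | None = None,
) -> SelectionResults:
    """Fit every demographic subset (2^m models) with the exposure forced in.

    Main effects only; each candidate model uses complete cases for its own
    covariates.  Ranked by AICc ascending with deterministic tie-breaks:
    fewer terms first, then lexicographic term names.
    """
    candidates = tuple(candidates)
    if not candidates:
        raise ValueError("need at least one demographic candidate")
    rows = []
    fits: dict = {}
    failures = []
    for m in range(len(candidates) + 1):
        for subset in combinations(candidates, m):
            try:
                y, X, _ = build_design(data, exposure, subset, references)
                fit = fit_poisson(y, X)
            except Exception as exc:  # noqa: BLE001 - record and keep searching
                failures.append((subset, exc))
                continue
            fits[subset] = fit
            rows.append(
                {
                    "demographics": subset,
                    "terms": fit.terms,
                    "k": fit.k,
                    "n": fit.n_used,
                    "aic": fit.aic,
                    "aicc": fit.aicc,
                }
            )
    if not rows:
        raise RuntimeError(f"all {len(failures)} candidate fits failed; first error: {failures[0][1]}")
    table = pd.DataFrame(rows)
    table["_tie"] = table["demographics"].map(lambda t: ",".join(t))
    table = table.sort_values(["aicc", "k", "_tie"], ignore_index=True).drop(columns="_tie")
    table["rank"] = np.arange(1, len(table) + 1)
    table["model_id"] = table["demographics"].map(lambda t: "exposure+" + "+".join(t) if t else "exposure_only")
    return SelectionResults(table=table, fits=fits)


class PoissonExposureResults:
    """Results of one fitted exposure model; thin wrapper over :class:`GlmFit`."""

    def __init__(self, model: "PoissonExposureModel", fit: GlmFit):
        self.model = model
        self._fit = fit
        self.params = {t: v[0] for t, v in fit.coefficients.items()}
        self.bse = {t: v[1] for t, v in fit.coefficients.items()}
        self.zvalues = {t: v[2] for t, v in fit.coefficients.items()}
        self.pvalues = {t: v[3] for t, v in fit.coefficients.items()}
        self.llf = fit.log_likelihood
        self.aic = fit.aic
        self.aicc = fit.aicc
        self.nobs = fit.n_used
        self.df_resid = fit.residual_df

    @property
    def glm_fit(self) -> GlmFit:
        return self._fit

    def coefficient_table(self) -> pd.DataFrame:
        return self._fit.to_frame()

    def to_dict(self) -> dict:
        return {
            "exposure": self.model.exposure,
            "coefficients": {
                t: {"estimate": e, "std_error": se, "z": z, "p_value": p}
                for t, (e, se, z, p) in self._fit.coefficients.items()
            },
            "log_likelihood": self.llf,
            "aic": self.aic,
            "aicc": self.aicc,
            "n": self.nobs,
            "residual_df": self.df_resid,
        }

    def summary(self) -> str:
        head = (
            f"Poisson GLM: symptom_total ~ {self.model.exposure}"
            + ("".join(f" + {d}" for d in self.model.demographics))
            + f"\n  n = {self.nobs}, residual df = {self.df_resid}, "
            + f"AIC = {self.aic:.2f}, AICc = {self.aicc:.2f}\n"
        )
        tab = self.coefficient_table()
        body = tab.to_string(index=False, float_format=lambda v: f"{v:10.4f}")
        return head + body


class PoissonExposureModel:
    """Poisson GLM of total symptom count on one exposure measure.

    Parameters
    ----------
    data : DataFrame
        One row per respondent with a ``symptom_total`` column (or binary
        ``sym_*`` columns from which it is derived), the exposure column and
        any demographic columns.
    exposure : str
        Name of the exposure column (always included in the fit).
    demographics : sequence of str
        Covariates to adjust for; subset of ``age, sex, smoker, water_source``
        or any numeric column.
    references : dict, optional
        Reference level per categorical covariate (defaults: sex=male,
        smoker=never, water_source=municipal).
    """

    def __init__(self, data: pd.DataFrame, exposure: str, demographics=(), references: dict | None = None):
        data = data.copy()
        if "symptom_total" not in data.columns:
            from .cohort import symptom_columns

            cols = symptom_columns(data)
            if not cols:
                raise ValueError("data needs a symptom_total column or sym_* columns")
            data["symptom_total"] = data[cols].sum(axis=1)
        if exposure not in data.columns:
            raise ValueError(f"exposure column {exposure!r} not in data")
        self.data = data
        self.exposure = exposure
        self.demographics = tuple(demographics)
        self.references = references

    @classmethod
    def from_dataframe(cls, data, exposure, demographics=(), references=None):
        return cls(data, exposure, demographics, references)

    def fit(self) -> PoissonExposureResults:
        y, X, _ = build_design(self.data, self.exposure, self.demographics, self.references)
        return PoissonExposureResults(self, fit_poisson(y, X))

    def select_demographics(self, candidates=DEMOGRAPHIC_CANDIDATES) -> SelectionResults:
        return exhaustive_selection(self.data, self.exposure, candidates, self.references)


def spatial_scale_selection(
    respondents: pd.DataFrame,
    wells: pd.DataFrame,
    radii=(1.0, 2.0, 5.0),
    demographics=(),
    references: dict | None = None,
    match_year: bool = True,
):
    """Compare buffer radii for the well-density exposure by AIC.

    For each radius the cumulative well density is recomputed per respondent,
    the same Poisson model form fitted, and the radius with the lowest AIC
    selected.  Returns ``(table, selected_radius_km)`` with one row per radius.
    """
    from . import geo

    radii = tuple(radii)
    if not radii:
        raise ValueError("radii must be non-empty")
    data = respondents.copy()
    D = geo.pairwise_distances_km(
        (data["lat"].to_numpy(float), data["lon"].to_numpy(float)),
        (wells["lat"].to_numpy(float), wells["lon"].to_numpy(float)),
    )
    if match_year:
        year_ok = data["year"].to_numpy(int)[:, None] == wells["year"].to_numpy(int)[None, :]
    else:
        year_ok = np.ones_like(D, dtype=bool)
    rows = []
    for r in radii:
        data["cwd_scale"] = ((D <= r) & year_ok).sum(axis=1) / (np.pi * r**2)
        fit = PoissonExposureModel(data, "cwd_scale", demographics, references).fit()
        rows.append({"radius_km": r, "aic": fit.aic, "aicc": fit.aicc, "n": fit.nobs})
    table = pd.DataFrame(rows)
    selected = float(table.loc[table["aic"].idxmin(), "radius_km"])
    return table, selected
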