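"""Cohort construction from health-assessment records.

Records arrive pre-coded: one row per respondent with demographics, a binary
column per symptom, and boolean exclusion flags set upstream during record
review.  Exclusion runs in two audited stages, mirroring the usual flow of a
retrospective records study:

* stage 1 — review-based exclusions (minors, industry workers, out-of-state
  residents, incomplete assessments);
* stage 2 — analysis restrictions (no usable residence coordinates).

The clinician plausibility review that strikes individual symptoms (those
explainable by co-occurring conditions) cannot be algorithmised; it enters
as pre-zeroed symptom columns or explicit override columns, see
:func:`apply_symptom_overrides`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml

CATEGORIES = (
    "general",
    "lung and heart",
    "skin",
    "EENT",
    "GI",
    "nerves and muscle",
    "reproductive",
    "blood system",
    "psychological",
)

STAGE1_FLAGS = ("flag_under_18", "flag_industry_worker", "flag_outside_pa", "flag_incomplete")
STAGE2_FLAGS = ("flag_no_coordinates",)

SYMPTOM_PREFIX = "sym_"

__all__ = [
    "CATEGORIES",
    "STAGE1_FLAGS",
    "STAGE2_FLAGS",
    "SYMPTOM_PREFIX",
    "ExclusionAudit",
    "SymptomDictionary",
    "symptom_columns",
    "apply_stage1_exclusions",
    "apply_stage2_exclusions",
    "apply_symptom_overrides",
    "symptom_total",
    "frequency_table",
    "category_summary",
]


@dataclass
class ExclusionAudit:
    """Counts for one exclusion stage: ``retained + removed == n_input`` always."""

    stage: str
    n_input: int
    n_removed: int
    n_retained: int

    def to_dict(self) -> dict:
        return asdict(self)


class SymptomDictionary:
    """Mapping from symptom name to one of the nine symptom categories."""

    def __init__(self, mapping: dict):
        bad = {s: c for s, c in mapping.items() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown categories: {bad}")
        self.mapping = dict(mapping)

    def __getitem__(self, symptom: str) -> str:
        if symptom not in self.mapping:
            raise KeyError(f"symptom {symptom!r} not in dictionary")
        return self.mapping[symptom]

    def __contains__(self, symptom: str) -> bool:
        return symptom in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    @classmethod
    def default(cls) -> "SymptomDictionary":
        """The dictionary shipped with the package (editable YAML data file)."""
        text = resources.files("shalehealth.data").joinpath("symptom_categories.yaml").read_text()
        return cls(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "SymptomDictionary":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def symptom_columns(records: pd.DataFrame) -> list[str]:
    """Columns of ``records`` holding binary symptom indicators (``sym_`` prefix)."""
    return [c for c in records.columns if c.startswith(SYMPTOM_PREFIX)]


def _apply_flags(records: pd.DataFrame, flags, stage: str):
    present = [f for f in flags if f in records.columns]
    if present:
        removed_mask = records[present].astype(bool).any(axis=1)
    else:
        removed_mask = pd.Series(False, index=records.index)
    kept = records.loc[~removed_mask].copy()
    audit = ExclusionAudit(
        stage=stage,
        n_input=len(records),
        n_removed=int(removed_mask.sum()),
        n_retained=len(kept),
    )
    return kept, audit


def apply_stage1_exclusions(records: pd.DataFrame):
    """Drop rows carrying any review-stage flag (minor, industry worker, out of
    state, incomplete form); returns ``(filtered, ExclusionAudit)``.  Idempotent."""
    return _apply_flags(records, STAGE1_FLAGS, "stage1")


def apply_stage2_exclusions(records: pd.DataFrame):
    """Drop rows without usable residence coordinates; returns ``(filtered, audit)``.

    Rows are removed if ``flag_no_coordinates`` is set or lat/lon are missing.
    """
    records = records.copy()
    if "lat" in records.columns and "lon" in records.columns:
        no_coords = records["lat"].isna() | records["lon"].isna()
        if "flag_no_coordinates" in records.columns:
            records["flag_no_coordinates"] = records["flag_no_coordinates"].astype(bool) | no_coords
        else:
            records["flag_no_coordinates"] = no_coords
    return _apply_flags(records, STAGE2_FLAGS, "stage2")


def apply_symptom_overrides(records: pd.DataFrame, overrides: pd.DataFrame) -> pd.DataFrame:
    """Zero out symptom entries struck during clinician review.

    ``overrides`` is a binary matrix aligned with the symptom columns of
    ``records`` (1 = symptom implausible for that respondent, set to 0).
    """
    out = records.copy()
    for col in overrides.columns:
        if col in out.columns:
            out[col] = out[col].where(~overrides[col].astype(bool), 0)
    return out


def symptom_total(record) -> int:
    """Number of symptoms reported by one respondent (sum of the binary vector)."""
    if isinstance(record, pd.Series):
        cols = [c for c in record.index if c.startswith(SYMPTOM_PREFIX)]
        vec = record[cols] if cols else record
    else:
        vec = record
    arr = np.asarray(vec, dtype=float)
    if not np.all(np.isin(arr, (0.0, 1.0))):
        raise ValueError("symptom vector must be binary 0/1")
    return int(arr.sum())


def _round_half_up(x) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def frequency_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-symptom reporter count and integer percentage, sorted descending.

    Percentages are ``round_half_up(100 * n_symptom / n_respondents)``; ties
    in count break alphabetically for a deterministic ordering.
    """
    cols = symptom_columns(records)
    if len(records) == 0 or not cols:
        raise ValueError("frequency_table needs at least one respondent and one symptom column")
    n = len(records)
    counts = records[cols].sum().astype(int)
    out = pd.DataFrame(
        {
            "symptom": [c[len(SYMPTOM_PREFIX):] for c in cols],
            "n": counts.to_numpy(),
            "percent": _round_half_up(100.0 * counts.to_numpy() / n),
        }
    )
    return out.sort_values(["n", "symptom"], ascending=[False, True], ignore_index=True)


def category_summary(symptoms, dictionary: SymptomDictionary) -> pd.DataFrame:
    """Counts and shares of the nine categories over a list of symptom names.

    ``symptoms`` may be a list of names or a records DataFrame (in which case
    the symptom columns define the list).  Shares are fractions summing to 1
    over categorised symptoms; ``percent`` is the half-up rounded display value.
    """
    if isinstance(symptoms, pd.DataFrame):
        names = [c[len(SYMPTOM_PREFIX):] for c in symptom_columns(symptoms)]
    else:
        names = list(symptoms)
    unknown = [s for s in names if s not in dictionary]
    if unknown:
        raise KeyError(f"symptoms not in dictionary: {unknown}")
    counts = {c: 0 for c in CATEGORIES}
    for s in names:
        counts[dictionary[s]] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no symptoms to summarise")
    rows = [
        {
            "category": c,
            "n": counts[c],
            "share": counts[c] / total,
            "percent": int(_round_half_up(100.0 * counts[c] / total)),
        }
        for c in CATEGORIES
    ]
    return pd.DataFrame(rows)
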