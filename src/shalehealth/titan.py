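"""Threshold Indicator Taxa Analysis (TITAN) for binary symptoms on an exposure gradient.

TITAN, originally an ecological community method, scores how sharply each
binary response (here: a reported symptom) partitions along a continuous
environmental gradient (here: a respondent-level exposure measure).  For a
candidate change point splitting respondents into a low-exposure and a
high-exposure group, each symptom gets Dufrêne–Legendre indicator values

    IndVal_g = 100 * A_g * B_g

where ``A_g`` (specificity) is the mean occurrence in group ``g`` divided by
the summed mean occurrences of both groups, and ``B_g`` (fidelity) is the
proportion of group-``g`` respondents reporting the symptom.  For 0/1 data
``B_g`` equals the group occurrence rate, so ``IndVal_g = 100 * m_g^2 /
(m_lo + m_hi)`` with ``m_g`` the group means.  The change point maximising
the larger of the two group indicator values is the symptom's threshold; the
symptom is a *positive* indicator if the high-exposure group is the
indicated one, *inverse* otherwise.

Significance comes from a permutation test of the maximised indicator value
(gradient labels shuffled), summarised as a z-score and an add-one
permutation p-value.  Bootstrap resampling of respondents yields two
stability diagnostics: *purity* (share of replicates reproducing the
observed direction) and *reliability* (share with permutation p ≤ 0.05).

Use :class:`TitanModel` / :class:`TitanResults` for the full analysis, or
the module functions (:func:`indval`, :func:`best_changepoint`,
:func:`permutation_z`, :func:`bootstrap_diagnostics`, :func:`run_titan`)
for the pieces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TitanModel",
    "TitanResults",
    "TitanSymptomResult",
    "indval",
    "best_changepoint",
    "permutation_z",
    "bootstrap_diagnostics",
    "run_titan",
    "report_filter",
]


@dataclass
class TitanSymptomResult:
    """Change-point summary for one symptom along one exposure gradient."""

    symptom: str
    frequency: int
    change_point: float
    indicator_value: float
    direction: str  # "positive" | "inverse"
    z_score: float
    p_value: float
    purity: float
    reliability: float
    significant: bool


# ---------------------------------------------------------------------------
# Core computations
# ---------------------------------------------------------------------------


def indval(occurrence, grouping):
    """Dufrêne–Legendre indicator values of a binary vector for a 2-group partition.

    Parameters
    ----------
    occurrence : array of 0/1
    grouping : boolean array, ``True`` marking the second (upper) group.

    Returns
    -------
    (indval_lower, indval_upper), best_group
        Indicator values on the 0–100 scale and the index (0 or 1) of the
        indicated group (ties go to the upper group).
    """
    occ = np.asarray(occurrence, dtype=float)
    grp = np.asarray(grouping, dtype=bool)
    if occ.shape != grp.shape:
        raise ValueError("occurrence and grouping must have equal length")
    if not np.all(np.isin(occ, (0.0, 1.0))):
        raise ValueError("occurrence must be binary 0/1")
    n_up = int(grp.sum())
    if n_up == 0 or n_up == occ.size:
        raise ValueError("both groups must be non-empty")
    if occ.sum() == 0:
        raise ValueError("indicator value undefined for all-zero occurrence")
    m_lo = occ[~grp].mean()
    m_up = occ[grp].mean()
    denom = m_lo + m_up
    iv_lo = 100.0 * m_lo * m_lo / denom
    iv_up = 100.0 * m_up * m_up / denom
    return (iv_lo, iv_up), (1 if iv_up >= iv_lo else 0)


def _valid_splits(g_sorted: np.ndarray, min_split: int) -> np.ndarray:
    """Left-group sizes i of admissible splits: min_split ≤ i ≤ n-min_split and
    the flanking sorted gradient values are distinct."""
    n = g_sorted.size
    i = np.arange(min_split, n - min_split + 1)
    return i[g_sorted[i - 1] < g_sorted[i]]


def _max_indval_batch(occ_sorted: np.ndarray, splits: np.ndarray):
    """Best split per row of a batch of gradient-ordered occurrence vectors.

    ``occ_sorted`` is (B, n); ``splits`` the admissible left-group sizes.
    Returns ``(score, split_pos, upper_indicated)`` each of shape (B,):
    the maximised IndVal, the index into ``splits`` of the (first) maximiser
    — ascending split order makes ties resolve toward the lowest change
    point — and whether the upper group is the indicated one there.
    """
    n = occ_sorted.shape[1]
    T = occ_sorted.sum(axis=1, keepdims=True)
    C = np.cumsum(occ_sorted, axis=1)
    TL = C[:, splits - 1]
    m_lo = TL / splits
    m_up = (T - TL) / (n - splits)
    denom = m_lo + m_up
    with np.errstate(invalid="ignore", divide="ignore"):
        iv = 100.0 * np.maximum(m_lo, m_up) ** 2 / denom
    iv = np.where(denom > 0, iv, 0.0)
    pos = np.argmax(iv, axis=1)
    rows = np.arange(occ_sorted.shape[0])
    score = iv[rows, pos]
    upper = m_up[rows, pos] >= m_lo[rows, pos]
    return score, pos, upper


def _prepare(occurrence, gradient, min_split):
    occ = np.asarray(occurrence, dtype=float)
    g = np.asarray(gradient, dtype=float)
    if occ.shape != g.shape or occ.ndim != 1:
        raise ValueError("occurrence and gradient must be 1-d of equal length")
    if occ.size < 2 * min_split:
        raise ValueError(f"need at least {2 * min_split} samples for min_split={min_split}")
    if not np.all(np.isfinite(g)):
        raise ValueError("gradient must be finite")
    if not np.all(np.isin(occ, (0.0, 1.0))):
        raise ValueError("occurrence must be binary 0/1")
    if occ.sum() == 0:
        raise ValueError("indicator value undefined for all-zero occurrence")
    order = np.argsort(g, kind="stable")
    g_sorted = g[order]
    splits = _valid_splits(g_sorted, min_split)
    if splits.size == 0:
        raise ValueError("no admissible change point (gradient too coarse or constant)")
    return occ[order], g_sorted, splits


def best_changepoint(occurrence, gradient, min_split: int = 5):
    """Exposure change point maximising the indicator value of one symptom.

    All splits between consecutive distinct sorted gradient values leaving at
    least ``min_split`` respondents per side are scored; the change point is
    the midpoint of the values flanking the best split.  Ties in the maximum
    break toward the lowest change point.

    Returns ``(change_point, indicator_value, direction)`` with direction
    ``"positive"`` when the high-exposure group is the indicated one.
    """
    occ_sorted, g_sorted, splits = _prepare(occurrence, gradient, min_split)
    score, pos, upper = _max_indval_batch(occ_sorted[None, :], splits)
    i = splits[int(pos[0])]
    cp = 0.5 * (g_sorted[i - 1] + g_sorted[i])
    return float(cp), float(score[0]), ("positive" if upper[0] else "inverse")


def permutation_z(occurrence, gradient, min_split: int = 5, n_perm: int = 250, seed=None):
    """Permutation z-score and p-value for a symptom's maximised indicator value.

    The gradient is permuted ``n_perm`` times (equivalently, the occurrence
    vector is shuffled against the sorted gradient) and the maximised IndVal
    recomputed; ``z = (obs - mean) / sd`` over the permutation maxima and
    ``p = (1 + #{perm >= obs}) / (n_perm + 1)`` (add-one estimator, never 0).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    occ_sorted, _, splits = _prepare(occurrence, gradient, min_split)
    obs, _, _ = _max_indval_batch(occ_sorted[None, :], splits)
    obs = float(obs[0])
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(occ_sorted, (n_perm, 1)), axis=1)
    null, _, _ = _max_indval_batch(perm, splits)
    sd = float(null.std())
    if sd == 0.0:
        raise ValueError("degenerate permutation null: zero variance")
    z = (obs - float(null.mean())) / sd
    return float(z), _perm_pvalue(null, obs, n_perm)


def _perm_pvalue(null: np.ndarray, obs: float, n_perm: int) -> float:
    """Add-one mid-p permutation p-value.

    With 0/1 responses the maximised IndVal is discrete and exact ties
    between observed and permuted values are common (~4% of permutations at
    n ~ 100); counting every tie as "as extreme" makes the test noticeably
    conservative, so ties get half weight (the mid-p convention).  The
    add-one term keeps p strictly positive.
    """
    greater = float(np.count_nonzero(null > obs + 1e-9))
    ties = float(np.count_nonzero(np.abs(null - obs) <= 1e-9))
    return (1.0 + greater + 0.5 * ties) / (n_perm + 1.0)


def bootstrap_diagnostics(
    occurrence,
    gradient,
    min_split: int = 5,
    n_boot: int = 500,
    n_perm: int = 250,
    seed=None,
    alpha: float = 0.05,
):
    """Bootstrap stability of a symptom's change-point direction and significance.

    Respondents are resampled with replacement ``n_boot`` times; *purity* is
    the share of replicates whose indicated direction matches the observed
    one, *reliability* the share whose permutation p-value is ≤ ``alpha``.
    Replicates where the indicator value is undefined (no reporters drawn, or
    no admissible split) count as neither matching nor significant.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    occ = np.asarray(occurrence, dtype=float)
    g = np.asarray(gradient, dtype=float)
    occ_sorted, _, base_splits = _prepare(occ, g, min_split)
    _, _, obs_upper = _max_indval_batch(occ_sorted[None, :], base_splits)
    obs_dir = bool(obs_upper[0])
    rng = np.random.default_rng(seed)
    n = occ.size
    match = 0
    signif = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ob, gb = occ[idx], g[idx]
        if ob.sum() == 0:
            continue
        order = np.argsort(gb, kind="stable")
        gs, os_ = gb[order], ob[order]
        splits = _valid_splits(gs, min_split)
        if splits.size == 0:
            continue
        score, _, upper = _max_indval_batch(os_[None, :], splits)
        if bool(upper[0]) == obs_dir:
            match += 1
        perm = rng.permuted(np.tile(os_, (n_perm, 1)), axis=1)
        null, _, _ = _max_indval_batch(perm, splits)
        if _perm_pvalue(null, float(score[0]), n_perm) <= alpha:
            signif += 1
    return match / n_boot, signif / n_boot


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class TitanResults:
    """Per-symptom TITAN results; ``table`` has one row per analysed symptom."""

    REPORT_COLUMNS = [
        "symptom",
        "frequency",
        "change_point",
        "indicator_value",
        "direction",
        "z_score",
        "p_value",
        "purity",
        "reliability",
        "significant",
    ]

    def __init__(self, model: "TitanModel", table: pd.DataFrame):
        self.model = model
        self.table = table

    def report_filter(
        self, min_frequency_report: int = 10, min_z: float = 1.0, alpha: float = 0.05
    ) -> pd.DataFrame:
        return report_filter(self.table, min_frequency_report, min_z, alpha)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> str:
        n_sig = int(self.table["significant"].sum())
        lines = [
            f"TITAN: {len(self.table)} symptoms analysed along '{self.model.gradient_name}', "
            f"{n_sig} significant at alpha={self.model.alpha}",
            "-" * 72,
        ]
        tab = self.table.sort_values("indicator_value", ascending=False)
        for _, r in tab.iterrows():
            lines.append(
                f"{r['symptom']:<28} f={r['frequency']:>3}  cp={r['change_point']:9.4f}  "
                f"IndVal={r['indicator_value']:6.2f}  {r['direction']:<8}  "
                f"z={r['z_score']:5.2f}  p={r['p_value']:.4f}"
            )
        return "\n".join(lines)

    def plot_spectrum(self, ax=None, filtered: bool = True, **filter_kwargs):
        """Horizontal bar chart of indicator values, bar height ∝ symptom frequency,
        positive and inverse indicators on opposite sides."""
        import matplotlib.pyplot as plt

        tab = self.report_filter(**filter_kwargs) if filtered else self.table
        tab = tab.sort_values("indicator_value")
        if ax is None:
            _, ax = plt.subplots(figsize=(7, max(2, 0.35 * len(tab))))
        if len(tab):
            sign = np.where(tab["direction"] == "positive", 1.0, -1.0)
            widths = 0.2 + 0.6 * tab["frequency"] / tab["frequency"].max()
            ax.barh(
                np.arange(len(tab)),
                sign * tab["indicator_value"],
                height=widths,
                color=np.where(sign > 0, "#2166ac", "#b2182b"),
            )
            ax.set_yticks(np.arange(len(tab)), tab["symptom"])
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("indicator value (inverse ← 0 → positive)")
        ax.set_title(f"Symptom indicators along {self.model.gradient_name}")
        return ax


class TitanModel:
    """TITAN analysis of a binary symptom matrix along one exposure gradient.

    Parameters
    ----------
    symptoms : DataFrame of 0/1, one column per symptom
    gradient : 1-d exposure values, one per respondent (finite, non-constant)
    min_frequency : minimum number of reporters for a symptom to be analysed
    min_split : minimum respondents on each side of a candidate change point
    alpha : significance level for the per-symptom permutation test
    """

    def __init__(
        self,
        symptoms: pd.DataFrame,
        gradient,
        min_frequency: int = 5,
        min_split: int = 5,
        alpha: float = 0.05,
        gradient_name: str = "exposure",
    ):
        gradient = np.asarray(gradient, dtype=float)
        if len(symptoms) != gradient.size:
            raise ValueError("symptom matrix and gradient must have equal length")
        if not np.all(np.isfinite(gradient)):
            raise ValueError("gradient must be finite")
        if np.min(gradient) == np.max(gradient):
            raise ValueError("gradient is constant; no change point is identifiable")
        self.symptoms = symptoms
        self.gradient = gradient
        self.min_frequency = min_frequency
        self.min_split = min_split
        self.alpha = alpha
        self.gradient_name = gradient_name

    def fit(self, n_perm: int = 250, n_boot: int = 500, seed=None) -> TitanResults:
        """Run the analysis; ``n_boot=0`` skips the bootstrap diagnostics (NaN)."""
        freq = self.symptoms.sum(axis=0)
        keep = [c for c in self.symptoms.columns if freq[c] >= self.min_frequency]
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        children = ss.spawn(2 * len(keep))
        rows = []
        for j, col in enumerate(keep):
            occ = self.symptoms[col].to_numpy(float)
            cp, iv, direction = best_changepoint(occ, self.gradient, self.min_split)
            z, p = permutation_z(
                occ, self.gradient, self.min_split, n_perm=n_perm, seed=children[2 * j]
            )
            if n_boot:
                purity, reliability = bootstrap_diagnostics(
                    occ,
                    self.gradient,
                    self.min_split,
                    n_boot=n_boot,
                    n_perm=n_perm,
                    seed=children[2 * j + 1],
                    alpha=self.alpha,
                )
            else:
                purity = reliability = float("nan")
            rows.append(
                TitanSymptomResult(
                    symptom=col,
                    frequency=int(freq[col]),
                    change_point=cp,
                    indicator_value=iv,
                    direction=direction,
                    z_score=z,
                    p_value=p,
                    purity=purity,
                    reliability=reliability,
                    significant=p <= self.alpha,
                ).__dict__
            )
        table = pd.DataFrame(rows, columns=TitanResults.REPORT_COLUMNS)
        return TitanResults(self, table)


def run_titan(
    symptoms: pd.DataFrame,
    gradient,
    min_frequency: int = 5,
    min_split: int = 5,
    n_perm: int = 250,
    n_boot: int = 500,
    seed=None,
    alpha: float = 0.05,
    gradient_name: str = "exposure",
) -> pd.DataFrame:
    """One-call TITAN: returns the per-symptom result table (see :class:`TitanModel`)."""
    model = TitanModel(
        symptoms,
        gradient,
        min_frequency=min_frequency,
        min_split=min_split,
        alpha=alpha,
        gradient_name=gradient_name,
    )
    return model.fit(n_perm=n_perm, n_boot=n_boot, seed=seed).table


def report_filter(
    results: pd.DataFrame,
    min_frequency_report: int = 10,
    min_z: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Reporting filter: keep significant symptoms with frequency strictly greater
    than ``min_frequency_report`` and z-score ≥ ``min_z``; sort by indicator value
    descending.  Direction is retained for plotting positive vs inverse panels."""
    if len(results) == 0:
        raise ValueError("results table is empty")
    keep = (
        (results["p_value"] <= alpha)
        & (results["frequency"] > min_frequency_report)
        & (results["z_score"] >= min_z)
    )
    return results.loc[keep].sort_values("indicator_value", ascending=False, ignore_index=True)
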