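"""Cohort ingestion, PHQ-9 scoring, log10 transform, and descriptive statistics.

Depressive symptoms are screened with the nine-item PHQ-9 (items scored 0-3,
total 0-27); a total of 10 or more flags depressive symptoms.  Descriptives
compare depressed vs non-depressed groups with the Mann-Whitney test for
continuous variables, Kruskal-Wallis for the ordered income category, and
the chi-square test for binary/unordered categories, and summarize metal
co-exposure with the pairwise Spearman matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PHQ9_CUTOFF",
    "score_phq9",
    "cronbach_alpha",
    "log10_metals",
    "describe",
    "final_sample_size",
    "DescriptivesReport",
]

PHQ9_CUTOFF = 10
_N_ITEMS = 9

CONTINUOUS_COVARIATES = ["age", "bmi"]
ORDERED_COVARIATES = ["income"]
CATEGORICAL_COVARIATES = ["sex", "smoking", "alcohol", "physical_activity"]


def final_sample_size(n_completed: int, n_excluded: int) -> int:
    """Cohort attrition accounting: questionnaire completers minus exclusions."""
    if n_excluded < 0 or n_completed < 0:
        raise ValueError("counts must be non-negative")
    if n_excluded > n_completed:
        raise ValueError("cannot exclude more subjects than completed")
    return n_completed - n_excluded


def score_phq9(items) -> tuple:
    """Score PHQ-9 responses: total = sum of the nine items, flag = total >= 10.

    Accepts a length-9 sequence (returns scalars) or an (n, 9) array/DataFrame
    (returns arrays).  Any item outside {0,1,2,3} or a missing item raises a
    validation error identifying the item index.
    """
    arr = np.asarray(items, dtype=float)
    one_row = arr.ndim == 1
    if one_row:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != _N_ITEMS:
        raise ValueError(f"expected 9 PHQ-9 items, got shape {np.asarray(items).shape}")
    for j in range(_N_ITEMS):
        col = arr[:, j]
        bad = ~np.isin(col, [0, 1, 2, 3]) | ~np.isfinite(col)
        if bad.any():
            raise ValueError(
                f"PHQ-9 item {j + 1} has invalid value(s) "
                f"{np.unique(col[bad])}; items must be integers 0..3")
    total = arr.sum(axis=1).astype(int)
    depressed = (total >= PHQ9_CUTOFF).astype(int)
    if one_row:
        return int(total[0]), int(depressed[0])
    return total, depressed


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum of item variances / variance of totals).

    Internal-consistency coefficient of a k-item scale; the emulated screener
    reports alpha = 0.892 on real data.  Variances use the n-1 denominator.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 and k >= 2")
    if not np.isfinite(X).all():
        raise ValueError("item matrix contains missing values")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha is undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def log10_metals(table: pd.DataFrame, metal_names: list[str]) -> pd.DataFrame:
    """log10-transform the metal columns (raw concentrations are right-skewed)."""
    X = table[metal_names].astype(float)
    bad = np.argwhere((X.to_numpy() <= 0) | ~np.isfinite(X.to_numpy()))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"non-positive concentration for subject index {X.index[i]} "
            f"metal {metal_names[j]!r}: {X.iloc[i, j]!r}")
    return np.log10(X)


@dataclass
class DescriptivesReport:
    """Group comparisons, outcome prevalence, and the metal Spearman matrix."""

    comparisons: pd.DataFrame  # variable, test, statistic, p_value
    prevalence: float          # proportion in [0, 1]
    prevalence_pct: float      # 100 * proportion, rounded to 2 decimals
    n_cases: int
    n_total: int
    spearman_matrix: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "comparisons": self.comparisons.to_dict(orient="records"),
            "prevalence": self.prevalence,
            "prevalence_pct": self.prevalence_pct,
            "n_cases": self.n_cases,
            "n_total": self.n_total,
            "spearman_matrix": self.spearman_matrix.to_dict(),
        }


def chi_square_independence(x, y, correction: bool = False):
    """Chi-square test of independence on the contingency table of x by y."""
    tab = pd.crosstab(pd.Series(x), pd.Series(y))
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return np.nan, np.nan
    res = stats.chi2_contingency(tab.to_numpy(), correction=correction)
    return float(res[0]), float(res[1])


def _mann_whitney(values: np.ndarray, group: np.ndarray):
    a, b = values[group == 1], values[group == 0]
    if len(a) == 0 or len(b) == 0:
        return np.nan, np.nan
    exact = len(a) <= 20 and len(b) <= 20
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def _kruskal(values: np.ndarray, group: np.ndarray):
    a, b = values[group == 1], values[group == 0]
    if len(a) == 0 or len(b) == 0:
        return np.nan, np.nan
    try:
        res = stats.kruskal(a, b)
    except ValueError:  # all values identical
        return 0.0, 1.0
    return float(res.statistic), float(res.pvalue)


def describe(table: pd.DataFrame, metal_names: list[str] | None = None,
             outcome: str = "depressed",
             income_test: str = "kruskal",
             chi2_correction: bool = False) -> DescriptivesReport:
    """Reproduce the descriptive table and correlation heat-map inputs.

    Continuous covariates get Mann-Whitney, the ordered income category gets
    Kruskal-Wallis by default (``income_test='chi2'`` switches to a frequency
    test), and binary/unordered categories get the chi-square test without
    continuity correction.  A group with zero members yields NaN statistics
    rather than an exception.  The Spearman matrix is computed on raw
    concentrations (it is rank-based, so the log10 transform is irrelevant).
    """
    if outcome not in table.columns:
        raise ValueError(f"outcome column {outcome!r} missing")
    y = table[outcome].to_numpy(dtype=int)
    rows = []
    for var in CONTINUOUS_COVARIATES:
        if var in table.columns:
            s, p = _mann_whitney(table[var].to_numpy(dtype=float), y)
            rows.append((var, "Mann-Whitney", s, p))
    for var in ORDERED_COVARIATES:
        if var in table.columns:
            if income_test == "chi2":
                s, p = chi_square_independence(table[var], y, chi2_correction)
                rows.append((var, "chi-square", s, p))
            else:
                s, p = _kruskal(table[var].to_numpy(dtype=float), y)
                rows.append((var, "Kruskal-Wallis", s, p))
    for var in CATEGORICAL_COVARIATES:
        if var in table.columns:
            s, p = chi_square_independence(table[var], y, chi2_correction)
            rows.append((var, "chi-square", s, p))
    comparisons = pd.DataFrame(rows, columns=["variable", "test", "statistic", "p_value"])

    n_total = len(y)
    n_cases = int(y.sum())
    prevalence = n_cases / n_total if n_total else np.nan

    if metal_names is None:
        metal_names = [m for m in table.columns
                       if m in set(table.columns) and table[m].dtype.kind == "f"
                       and m not in ("age", "bmi")]
    spearman = table[metal_names].corr(method="spearman") if metal_names else pd.DataFrame()

    return DescriptivesReport(
        comparisons=comparisons,
        prevalence=float(prevalence),
        prevalence_pct=float(round(100.0 * prevalence, 2)),
        n_cases=n_cases,
        n_total=n_total,
        spearman_matrix=spearman,
    )
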