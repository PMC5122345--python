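"""Clinical-cohort expression analysis: qPCR standard-curve
quantification, GOI/GAPDH normalization, high/low dichotomization at the
sample median (upper vs lower quartile pair), and the association tests
(Pearson chi-square for categorical features, Mann-Whitney U for
continuous ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "AssociationResult",
    "fit_standard_curve",
    "quantify",
    "dichotomize",
    "build_cohort_table",
    "test_categorical",
    "test_continuous",
]


@dataclass(frozen=True)
class StandardCurve:
    """qPCR calibration line: Ct = slope * log10(quantity) + intercept.

    A valid amplification curve has negative slope (Ct falls as template
    rises); ~ -3.32 corresponds to 100% PCR efficiency.
    """

    slope: float
    intercept: float
    r_squared: float = 1.0


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of a group-association test with per-group summaries."""

    test: str
    statistic: float
    p_value: float
    group_summaries: dict[str, float]


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Ct on log10(quantity) over serial dilutions.

    Requires at least 3 distinct positive quantities.
    """
    if len(points) < 3:
        raise ValueError("standard curve requires >= 3 dilution points")
    q = np.array([p[0] for p in points], dtype=float)
    ct = np.array([p[1] for p in points], dtype=float)
    if np.any(q <= 0):
        raise ValueError("quantities must be positive")
    if len(np.unique(q)) < 3:
        raise ValueError("standard curve requires >= 3 distinct quantities")
    fit = stats.linregress(np.log10(q), ct)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def quantify(ct: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Template quantity from a Ct value: 10^((ct - intercept) / slope)."""
    if curve.slope == 0:
        raise ValueError("standard curve slope must be nonzero")
    return 10.0 ** ((np.asarray(ct, dtype=float) - curve.intercept) / curve.slope)


def dichotomize(
    values: Sequence[float] | np.ndarray, cutoff: float | None = None
) -> np.ndarray:
    """Label each patient 'high' or 'low' expression.

    With no explicit cutoff the sample median splits the cohort (upper
    two quartiles vs lower two): strictly above the median -> high, ties
    at the median -> low. An explicit numeric cutoff replaces the median
    (still strictly-above -> high) for reproducing unequal published
    splits.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("dichotomization requires n >= 4 patients")
    if cutoff is None:
        if np.all(v == v[0]):
            raise ValueError("all expression values identical: no split exists")
        cutoff = float(np.median(v))
    return np.where(v > cutoff, "high", "low")


def build_cohort_table(
    table: pd.DataFrame,
    goi_curve: StandardCurve,
    gapdh_curve: StandardCurve,
    cutoff: float | None = None,
    goi_ct: str = "goi_ct",
    gapdh_ct: str = "gapdh_ct",
) -> pd.DataFrame:
    """Quantify GOI and GAPDH Ct columns, normalize, and label groups.

    Returns a copy of ``table`` with goi_value, gapdh_value,
    expression (= goi_value / gapdh_value) and group columns added.
    """
    out = table.copy()
    out["goi_value"] = quantify(out[goi_ct].to_numpy(), goi_curve)
    out["gapdh_value"] = quantify(out[gapdh_ct].to_numpy(), gapdh_curve)
    out["expression"] = out["goi_value"] / out["gapdh_value"]
    out["group"] = dichotomize(out["expression"].to_numpy(), cutoff)
    return out


def _split_groups(
    groups: Sequence[str] | np.ndarray, values: Sequence | np.ndarray
) -> tuple[np.ndarray, np.ndarray, str, str]:
    g = np.asarray(groups)
    v = np.asarray(values)
    if len(g) != len(v):
        raise ValueError("groups and feature values must align")
    labels = sorted(pd.unique(g), reverse=True)  # 'low' first? keep deterministic
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    a, b = labels
    return v[g == a], v[g == b], a, b


def test_categorical(
    groups: Sequence[str] | np.ndarray,
    feature: Sequence | np.ndarray,
    correction: bool = False,
) -> AssociationResult:
    """Pearson chi-square test of a binary feature across the two groups.

    No continuity correction by default; pass ``correction=True`` for
    Yates. Group summaries report the percentage of feature-positive
    patients per group. A zero row/column margin leaves the test
    undefined and raises.
    """
    g = np.asarray(groups)
    f = np.asarray(feature)
    table = pd.crosstab(g, f)
    if table.shape[0] != 2:
        raise ValueError(f"need exactly 2 groups, got {table.shape[0]}")
    if table.shape[1] == 1:
        raise ValueError("zero margin: the feature takes a single value")
    if table.shape[1] != 2:
        raise ValueError(f"need a binary feature, got {table.shape[1]} levels")
    obs = table.to_numpy()
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square test undefined")
    res = stats.chi2_contingency(obs, correction=correction)
    positive = table.columns[-1]
    summaries = {
        f"{grp}_pct_positive": 100.0 * table.loc[grp, positive] / table.loc[grp].sum()
        for grp in table.index
    }
    return AssociationResult(
        test="chi_square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=summaries,
    )


#: per-group size at or below which the exact Mann-Whitney null is used
EXACT_MW_MAX_N = 8


def test_continuous(
    groups: Sequence[str] | np.ndarray,
    values: Sequence[float] | np.ndarray,
) -> AssociationResult:
    """Two-sided Mann-Whitney U test of a numeric feature across groups.

    Exact null enumeration when both groups have <= 8 patients and no
    ties; otherwise the tie-corrected normal approximation. Group
    summaries report per-group medians.
    """
    va, vb, a, b = _split_groups(groups, np.asarray(values, dtype=float))
    if len(va) == 0 or len(vb) == 0:
        raise ValueError("both groups must be non-empty")
    method = (
        "exact"
        if len(va) <= EXACT_MW_MAX_N and len(vb) <= EXACT_MW_MAX_N
        else "asymptotic"
    )
    res = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method)
    return AssociationResult(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries={
            f"{a}_median": float(np.median(va)),
            f"{b}_median": float(np.median(vb)),
        },
    )
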