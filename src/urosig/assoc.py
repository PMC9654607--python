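"""Associations of the signature with mutational processes.

High/low signature groups are compared on mutational-signature
exposures (APOBEC SBS2/SBS13 versus non-APOBEC SBS4/SBS5 controls)
and neoantigen load by Mann–Whitney U tests, one per panel with no
multiplicity adjustment; neoantigen load is additionally regressed on
the continuous signature score by ordinary least squares.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MutationTable, SBS_COLUMNS
from .signature import ScoreTable
from .stratify import GroupAssignment

__all__ = [
    "AssociationResult",
    "RegressionResult",
    "mann_whitney_u",
    "linear_regression",
    "compare_exposures",
    "regress_neoantigens",
]


@dataclass
class AssociationResult:
    variable: str
    method: str       # mann_whitney_u | linear_regression | spearman
    statistic: float
    p_value: float
    effect: float     # U, slope, or rho


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_p: float
    exact_fit: bool = False


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney U (reported for group x) with a two-sided p.

    Exact enumeration when both groups have at most 8 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x with a two-sided t-test of slope = 0 (n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    scale = max(float(y @ y), 1.0)
    if rss <= 1e-12 * scale:
        return RegressionResult(slope, intercept, 0.0, exact_fit=True)
    se = math.sqrt(rss / (x.size - 2) / (xc @ xc))
    t = slope / se
    p = float(2.0 * stats.t.sf(abs(t), x.size - 2))
    return RegressionResult(slope, intercept, p)


def _aligned(df: pd.DataFrame, patient_ids: list[str], what: str) -> pd.DataFrame:
    have = set(df.index)
    want = set(patient_ids)
    if have != want:
        only_mt = sorted(have - want)[:5]
        only_other = sorted(want - have)[:5]
        raise ValueError(
            f"patient ID mismatch between mutation table and {what}: "
            f"mutation-only {only_mt}, {what}-only {only_other}")
    return df.loc[patient_ids]


def compare_exposures(
    mt: MutationTable, groups: GroupAssignment, log1p: bool = False,
) -> list[AssociationResult]:
    """Per-panel Mann–Whitney tests of high vs low signature groups.

    Tests each exposure column (SBS2, SBS13, SBS4, SBS5) and the
    neoantigen load, reporting U for the high group.  ``log1p``
    optionally transforms values first (rank tests are unaffected;
    provided for symmetry with the regression).
    """
    df = _aligned(mt.df, groups.patient_ids, "group assignment")
    labels = groups.series()
    high = labels == "high"
    low = labels == "low"
    if not high.any() or not low.any():
        raise ValueError("both groups must be non-empty")
    out = []
    for col in list(SBS_COLUMNS) + ["neoantigen_load"]:
        vals = df[col].to_numpy(float)
        if log1p:
            vals = np.log1p(vals)
        u, p = mann_whitney_u(vals[high.to_numpy()], vals[low.to_numpy()])
        out.append(AssociationResult(col, "mann_whitney_u", u, p, u))
    return out


def regress_neoantigens(
    mt: MutationTable, scores: ScoreTable, log1p: bool = False,
) -> AssociationResult:
    """OLS of neoantigen load (response) on the signature score."""
    df = _aligned(mt.df, scores.patient_ids, "score table")
    y = df["neoantigen_load"].to_numpy(float)
    if log1p:
        y = np.log1p(y)
    x = np.asarray(scores.score, float)
    if np.ptp(x) == 0:
        raise ValueError("constant score")
    fit = linear_regression(x, y)
    return AssociationResult("neoantigen_load", "linear_regression",
                             fit.slope, fit.slope_p, fit.slope)
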