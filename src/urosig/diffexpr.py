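"""Donor-blocked differential expression for the paired in vitro screen.

Genes responding to treatment are identified with a likelihood-ratio
test that accounts for matched genetic backgrounds: per gene, a full
ordinary-least-squares model (intercept + treatment + donor
indicators) is compared with a reduced model (intercept + donor
indicators) on log2(TPM+1) values.  The LRT statistic is
N * ln(RSS_reduced / RSS_full); p-values come from the exact F-test
equivalent of the nested comparison (df1 = 1, df2 = N - donors - 1),
which is exactly calibrated under Gaussian noise.  Benjamini–Hochberg
q-values control the FDR, and responsive genes are selected by strict
thresholds q < 0.05 and |log2FC| > 1 (i.e. more than two-fold).

With one control and one treated sample per donor the nested OLS
comparison reduces to closed forms in the per-donor treated-minus-
control differences d_i: RSS_reduced = sum d_i^2 / 2 and
RSS_full = sum (d_i - dbar)^2 / 2, which is how it is computed here
(vectorised over genes).
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, PairedDesign, Scale

logger = logging.getLogger("urosig")

__all__ = [
    "paired_lrt",
    "bh_adjust",
    "fold_changes",
    "select_responsive_genes",
    "differential_expression",
]

_RSS_TOL = 1e-12


def _paired_differences(m: ExpressionMatrix, design: PairedDesign) -> pd.DataFrame:
    """Per-gene, per-donor treated-minus-control differences (log scale)."""
    if m.scale is not Scale.LOG2P1:
        raise ValueError("expected log2(TPM+1) data; call log2p1_transform first")
    if design.n_donors < 2:
        raise ValueError("need at least 2 donors")
    for donor, (ctrl, trt) in design.pairs.items():
        if ctrl not in m.data.columns or trt not in m.data.columns:
            raise ValueError(f"donor {donor!r} has a pair member missing "
                             f"from the matrix")
    ctrl = m.data[design.control_ids()].to_numpy(float)
    trt = m.data[design.treated_ids()].to_numpy(float)
    return pd.DataFrame(trt - ctrl, index=m.data.index, columns=design.donors)


def paired_lrt(m: ExpressionMatrix, design: PairedDesign) -> pd.DataFrame:
    """Likelihood-ratio test of a treatment effect, blocked on donor.

    Returns a DataFrame indexed by gene with columns ``lrt_stat``,
    ``p_value`` and ``flag`` (empty, "constant" for genes with no
    variation to test, or "saturated" when the full model fits
    perfectly and p is reported as 0).
    """
    d = _paired_differences(m, design).to_numpy()
    n_donors = d.shape[1]
    n_samples = 2 * n_donors
    dbar = d.mean(axis=1)
    rss_full = ((d - dbar[:, None]) ** 2).sum(axis=1) / 2.0
    rss_reduced = (d ** 2).sum(axis=1) / 2.0

    scale = np.maximum(rss_reduced, 1.0)
    constant = rss_reduced <= _RSS_TOL * scale
    saturated = (~constant) & (rss_full <= _RSS_TOL * scale)

    lrt = np.zeros(len(d))
    p = np.ones(len(d))
    ok = ~constant & ~saturated
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss_reduced - rss_full)
                  / (rss_full / (n_samples - n_donors - 1)))
    lrt[ok] = n_samples * np.log(rss_reduced[ok] / rss_full[ok])
    p[ok] = stats.f.sf(f_stat[ok], 1, n_samples - n_donors - 1)
    lrt[saturated] = np.inf
    p[saturated] = 0.0

    flag = np.where(constant, "constant", np.where(saturated, "saturated", ""))
    return pd.DataFrame(
        {"lrt_stat": lrt, "p_value": p, "flag": flag}, index=m.data.index)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values, mapped
    back to the input order (stable under ties).
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("bh_adjust: empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fold_changes(m: ExpressionMatrix, design: PairedDesign) -> pd.Series:
    """Per-gene log2 fold-change: mean over donors of the paired
    treated-minus-control difference of log2(TPM+1)."""
    d = _paired_differences(m, design)
    return d.mean(axis=1).rename("log2fc")


def select_responsive_genes(
    results: pd.DataFrame,
    q_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
    direction: str = "up",
) -> list[str]:
    """Strict-threshold selection of responsive genes.

    up: q < q_max and log2fc > min_abs_log2fc;
    down: q < q_max and log2fc < -min_abs_log2fc.
    Output is sorted by descending |log2fc|.
    """
    if results.empty:
        raise ValueError("empty results table")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    q = results["q_value"]
    fc = results["log2fc"]
    if direction == "up":
        mask = (q < q_max) & (fc > min_abs_log2fc)
    else:
        mask = (q < q_max) & (fc < -min_abs_log2fc)
    hit = results.loc[mask]
    return list(hit.reindex(hit["log2fc"].abs()
                            .sort_values(ascending=False, kind="mergesort")
                            .index).index)


def differential_expression(
    m: ExpressionMatrix, design: PairedDesign,
) -> pd.DataFrame:
    """Full per-gene DE table: log2fc, lrt_stat, p_value, q_value, flag."""
    design.validate_against(m)
    lrt = paired_lrt(m, design)
    fc = fold_changes(m, design)
    out = lrt.assign(log2fc=fc, q_value=bh_adjust(lrt["p_value"].to_numpy()))
    return out[["log2fc", "lrt_stat", "p_value", "q_value", "flag"]]
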