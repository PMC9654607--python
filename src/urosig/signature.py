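"""Consensus signature refinement and single-value signature scoring.

A candidate gene set (IFNγ-responsive genes from the in vitro screen)
is refined against tumour cohorts: within each cohort the pairwise
Spearman correlation of every candidate with every other candidate is
computed, each gene is summarised by the median of its correlations,
and genes whose median correlation averaged across cohorts exceeds a
threshold (default 0.5, strict) form the signature — genes that are
both induced in vitro and tightly co-expressed in tumours.

Scoring: each signature gene's log-expression vector (across patients,
within one cohort) is scaled to unit Euclidean length, the scaled
values are summed per patient, and the sums are min–max rescaled to
[0, 1] to give the per-patient signature score.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, Scale

logger = logging.getLogger("urosig")

__all__ = [
    "GeneSignature",
    "ScoreTable",
    "spearman_rho",
    "pairwise_median_rho",
    "refine_signature",
    "unit_length_scale",
    "compute_scores",
    "rank_correlate_score",
]


@dataclass
class GeneSignature:
    """Refined gene signature plus the statistics that produced it.

    ``genes`` is ordered by descending mean (cross-cohort) median
    pairwise Spearman rho; ``per_cohort_median_rho`` keeps the
    per-cohort median correlation of every candidate (retained or not)
    so the filtering is auditable.
    """

    genes: list[str]
    rho_threshold: float
    per_cohort_median_rho: pd.DataFrame = field(default_factory=pd.DataFrame)
    mean_rho: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_cohort_median_rho.copy()
        out["mean_rho"] = self.mean_rho
        out["retained"] = [g in set(self.genes) for g in out.index]
        return out

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        # retained genes first, in signature order
        order = self.genes + [g for g in df.index if g not in set(self.genes)]
        df.loc[order].to_csv(path, sep="\t", index_label="gene_id",
                             float_format="%.6g", lineterminator="\n")

    @classmethod
    def read(cls, path: str | Path, rho_threshold: float = 0.5) -> "GeneSignature":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = list(df.index[df["retained"]])
        rho_cols = [c for c in df.columns if c not in ("mean_rho", "retained")]
        return cls(genes, rho_threshold, df[rho_cols], df["mean_rho"])


@dataclass
class ScoreTable:
    """Per-patient signature score in [0, 1] plus the pre-rescale sums."""

    patient_ids: list[str]
    raw_sum: np.ndarray
    score: np.ndarray
    cohort_label: str = ""

    def __post_init__(self) -> None:
        self.raw_sum = np.asarray(self.raw_sum, float)
        self.score = np.asarray(self.score, float)
        if not (len(self.patient_ids) == len(self.raw_sum) == len(self.score)):
            raise ValueError("ScoreTable fields must have equal length")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw_sum": self.raw_sum, "score": self.score,
             "cohort": self.cohort_label},
            index=pd.Index(self.patient_ids, name="patient_id"),
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g",
                               lineterminator="\n")

    @classmethod
    def read(cls, path: str | Path) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        label = str(df["cohort"].iloc[0]) if "cohort" in df else ""
        return cls(list(df.index.astype(str)), df["raw_sum"].to_numpy(),
                   df["score"].to_numpy(), label)

    def series(self) -> pd.Series:
        return pd.Series(self.score, index=self.patient_ids, name="score")


# ---------------------------------------------------------------------------
# correlation machinery


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (mean ranks for ties).

    Returns NaN for a constant input vector, which callers exclude
    from medians.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman_rho needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values)


def spearman_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs Spearman correlation of the rows of ``values``.

    Rows constant across columns yield NaN against every partner.
    """
    ranked = _rank_rows(np.asarray(values, float))
    constant = np.ptp(values, axis=1) == 0
    centred = ranked - ranked.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred ** 2).sum(axis=1))
    norms[constant] = np.nan
    with np.errstate(invalid="ignore"):
        corr = (centred @ centred.T) / np.outer(norms, norms)
    return np.clip(corr, -1.0, 1.0, out=corr)


def pairwise_median_rho(
    m: ExpressionMatrix, candidates: Sequence[str]
) -> pd.Series:
    """Median pairwise Spearman rho of each candidate with all others.

    For each candidate gene g present in ``m``, computes Spearman rho
    between g and every other present candidate and returns the median
    (self excluded; NaN pairs from constant genes excluded; the median
    of an even count is the midpoint of the central pair).
    """
    present = [g for g in candidates if g in m.data.index]
    absent = [g for g in candidates if g not in m.data.index]
    if absent:
        logger.warning("pairwise_median_rho: %d candidates absent, skipped: %s",
                       len(absent), absent[:10])
    if len(present) < 3:
        raise ValueError("need at least 3 candidate genes present in the matrix")
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    corr = spearman_matrix(m.data.loc[present].to_numpy())
    np.fill_diagonal(corr, np.nan)
    with np.errstate(all="ignore"):
        med = np.nanmedian(corr, axis=1)
    return pd.Series(med, index=present, name="median_rho")


def refine_signature(
    candidates: Sequence[str],
    cohorts: Mapping[str, ExpressionMatrix],
    rho_threshold: float = 0.5,
) -> GeneSignature:
    """Consensus refinement of a candidate gene set across cohorts.

    Candidates absent from any cohort are logged and dropped; each
    remaining gene is summarised per cohort by its median pairwise
    Spearman rho against the other candidates, the per-cohort medians
    are averaged, and genes with mean > ``rho_threshold`` (strict) are
    retained, ordered by descending mean rho (gene ID breaks ties).
    """
    if len(cohorts) < 2:
        raise ValueError("refinement requires at least 2 cohorts")
    shared = [g for g in candidates
              if all(g in m.data.index for m in cohorts.values())]
    dropped = [g for g in candidates if g not in set(shared)]
    if dropped:
        logger.warning("refine_signature: %d candidates absent from >=1 cohort, "
                       "dropped: %s", len(dropped), dropped[:10])
    per_cohort = pd.DataFrame(
        {name: pairwise_median_rho(m, shared) for name, m in cohorts.items()}
    )
    mean_rho = per_cohort.mean(axis=1)
    keep = mean_rho[mean_rho > rho_threshold]
    ordered = keep.sort_values(ascending=False, kind="mergesort")
    # deterministic ordering under exact rho ties
    ordered = ordered.iloc[
        np.lexsort((np.array(ordered.index, dtype=object), -ordered.to_numpy()))
    ]
    if ordered.empty:
        logger.warning("refine_signature: no gene exceeded rho_threshold=%.3g; "
                       "signature is empty", rho_threshold)
    return GeneSignature(list(ordered.index), rho_threshold, per_cohort, mean_rho)


# ---------------------------------------------------------------------------
# scoring


def unit_length_scale(v: np.ndarray) -> np.ndarray:
    """Scale a vector to unit Euclidean norm; an all-zero vector stays zero."""
    v = np.asarray(v, float)
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        logger.warning("unit_length_scale: all-zero vector contributes zeros")
        return np.zeros_like(v)
    return v / norm


def compute_scores(
    m: ExpressionMatrix, sig: GeneSignature | Sequence[str],
    cohort_label: str = "",
) -> ScoreTable:
    """Single-value signature score per patient.

    Each signature gene's row (across the cohort's patients) is scaled
    to unit length, the scaled rows are summed per patient, and the
    per-patient sums are rescaled to [0, 1].  Signature genes missing
    from the matrix are logged and scoring proceeds on the
    intersection; a cohort in which every patient has the same raw sum
    is degenerate and raises.
    """
    genes = list(sig.genes) if isinstance(sig, GeneSignature) else list(sig)
    if m.scale is Scale.TPM:
        raise ValueError("compute_scores expects log2p1 or array_intensity data")
    present = [g for g in genes if g in m.data.index]
    missing = [g for g in genes if g not in m.data.index]
    if missing:
        logger.warning("compute_scores: %d signature genes absent: %s",
                       len(missing), missing[:10])
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if m.shape[1] < 2:
        raise ValueError("need at least 2 patients to rescale scores")
    rows = m.data.loc[present].to_numpy(float)
    scaled = np.vstack([unit_length_scale(r) for r in rows])
    raw = scaled.sum(axis=0)
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        raise ValueError("degenerate cohort: all patients share one raw sum")
    score = (raw - lo) / (hi - lo)
    return ScoreTable(m.sample_ids, raw, score, cohort_label)


def _exact_spearman_p(rho: float, ry: np.ndarray, rx: np.ndarray) -> float:
    """Two-sided exact permutation p for small n (full enumeration)."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))
    rhos = (ry_c[perms] @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def rank_correlate_score(
    scores: ScoreTable, gene_values: np.ndarray
) -> tuple[float, float]:
    """Spearman correlation of the signature score with one gene.

    Mirrors the check that the score tracks IFNG expression in
    tumours.  The two-sided p uses the t approximation on n-2 df for
    n >= 10 and exact permutation enumeration below that; constant
    inputs return (nan, nan).
    """
    x = np.asarray(scores.score, float)
    y = np.asarray(gene_values, float)
    if len(x) != len(y):
        raise ValueError("score and gene vectors must align patient-for-patient")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    rho = spearman_rho(x, y)
    if math.isnan(rho):
        return float("nan"), float("nan")
    if n < 10:
        p = _exact_spearman_p(rho, stats.rankdata(y), stats.rankdata(x))
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(p)
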