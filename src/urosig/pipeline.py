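"""End-to-end orchestration of the signature pipeline.

``run_derivation`` goes from the paired in vitro experiment to a
refined signature: donor-blocked LRT -> BH correction -> strict
two-fold/q<0.05 selection of up-regulated candidates -> correlation-
consensus refinement across at least two tumour cohorts.

``run_cohort_analysis`` applies a signature to tumour cohorts:
scoring, two-group k-means stratification, pooled Kaplan–Meier
curves, Mantel-Cox and Gehan–Breslow–Wilcoxon tests, hazard ratios in
both forms, Cox regression on the continuous score, and (when a
mutation table is supplied) exposure/neoantigen associations.

Two pooling plans are supported, mirroring how mixed-platform cohorts
must be handled: ``pooled`` merges cohort matrices (shared genes)
into one matrix before scoring and clustering; ``separate`` scores
and clusters each cohort on its own and pools only the resulting
group labels and scores for survival analysis.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .assoc import AssociationResult, compare_exposures, regress_neoantigens
from .core_io import ClinicalTable, ExpressionMatrix, MutationTable, PairedDesign
from .diffexpr import differential_expression, select_responsive_genes
from .signature import GeneSignature, ScoreTable, compute_scores, refine_signature
from .stratify import GroupAssignment, kmeans2
from .survival import (CoxFit, HazardRatioEstimate, KMCurve, TwoGroupTest,
                       cox_ph, gehan_breslow_wilcoxon, hazard_ratio,
                       km_estimate, logrank_test)

logger = logging.getLogger("urosig")

__all__ = ["DerivationResult", "CohortAnalysis", "run_derivation",
           "run_cohort_analysis", "write_provenance"]


@dataclass
class DerivationResult:
    de_table: pd.DataFrame
    up_genes: list[str]
    down_genes: list[str]
    signature: GeneSignature
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class CohortAnalysis:
    scores: dict[str, ScoreTable]
    groups: dict[str, GroupAssignment]
    pooled_labels: pd.Series            # patient -> high/low across cohorts
    pooled_scores: pd.Series
    km_high: KMCurve
    km_low: KMCurve
    mantel_cox: TwoGroupTest
    wilcoxon: TwoGroupTest
    hr_mantel_haenszel: HazardRatioEstimate
    hr_logrank_oe: HazardRatioEstimate
    cox: CoxFit
    associations: list[AssociationResult] = field(default_factory=list)
    neoantigen_regression: AssociationResult | None = None

    def report(self) -> pd.DataFrame:
        rows = [
            ("mantel_cox", "chi_square", self.mantel_cox.chi_square),
            ("mantel_cox", "p", self.mantel_cox.p_value),
            ("gehan_breslow_wilcoxon", "chi_square", self.wilcoxon.chi_square),
            ("gehan_breslow_wilcoxon", "p", self.wilcoxon.p_value),
            ("hazard_ratio_mantel_haenszel", "hr", self.hr_mantel_haenszel.hr),
            ("hazard_ratio_logrank_oe", "hr", self.hr_logrank_oe.hr),
            ("cox", "beta", self.cox.beta),
            ("cox", "hr", self.cox.hr),
            ("cox", "p", self.cox.wald_p),
        ]
        for r in self.associations:
            rows.append((f"mwu_{r.variable}", "p", r.p_value))
        if self.neoantigen_regression is not None:
            rows.append(("neoantigen_regression", "slope",
                         self.neoantigen_regression.effect))
            rows.append(("neoantigen_regression", "p",
                         self.neoantigen_regression.p_value))
        return pd.DataFrame(rows, columns=["analysis", "quantity", "value"])


def run_derivation(
    invitro: ExpressionMatrix,
    design: PairedDesign,
    cohorts: Mapping[str, ExpressionMatrix],
    q_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
    rho_threshold: float = 0.5,
) -> DerivationResult:
    """In vitro screen -> candidate up-genes -> consensus signature."""
    from .core_io import Scale, log2p1_transform

    if invitro.scale is Scale.TPM:
        invitro = log2p1_transform(invitro)
    de = differential_expression(invitro, design)
    up = select_responsive_genes(de, q_max, min_abs_log2fc, "up")
    down = select_responsive_genes(de, q_max, min_abs_log2fc, "down")
    logger.info("derivation: %d genes tested, %d up, %d down",
                len(de), len(up), len(down))
    if not up:
        logger.warning("derivation: no up-regulated candidates; "
                       "signature will be empty")
        sig = GeneSignature([], rho_threshold)
    else:
        sig = refine_signature(up, cohorts, rho_threshold)
    logger.info("derivation: signature retains %d of %d candidates",
                len(sig), len(up))
    counts = {"tested": len(de), "up": len(up), "down": len(down),
              "signature": len(sig)}
    return DerivationResult(de, up, down, sig, counts)


def run_cohort_analysis(
    cohorts: Mapping[str, ExpressionMatrix],
    signature: GeneSignature,
    clinical: ClinicalTable,
    mutation: MutationTable | None = None,
    pooling: str = "separate",
    seed: int = 0,
    n_init: int = 50,
) -> CohortAnalysis:
    """Score, stratify and analyse survival for one or more cohorts.

    ``pooling='pooled'`` merges matrices before scoring/clustering
    (cohorts measured on one platform); ``'separate'`` scores and
    clusters each cohort independently and pools only labels and
    scores (mixed platforms).  ``clinical`` must cover the analysed
    patients; survival uses the pooled high/low labels and Cox the
    pooled continuous scores.
    """
    if pooling not in ("pooled", "separate"):
        raise ValueError("pooling must be 'pooled' or 'separate'")
    if pooling == "pooled" and len(cohorts) > 1:
        shared = None
        for m in cohorts.values():
            genes = set(m.data.index)
            shared = genes if shared is None else shared & genes
        shared = sorted(shared)
        merged = pd.concat(
            [m.data.loc[shared] for m in cohorts.values()], axis=1)
        scale = next(iter(cohorts.values())).scale
        cohorts = {"pooled": ExpressionMatrix(merged, scale)}

    scores: dict[str, ScoreTable] = {}
    groups: dict[str, GroupAssignment] = {}
    for name, m in cohorts.items():
        st = compute_scores(m, signature, cohort_label=name)
        ga = kmeans2(m.subset_genes(signature.genes), st,
                     seed=seed, n_init=n_init)
        scores[name] = st
        groups[name] = ga

    pooled_labels = pd.concat([g.series() for g in groups.values()])
    pooled_scores = pd.concat([s.series() for s in scores.values()])

    clin = clinical.subset(list(pooled_labels.index))
    high = clin.subset(list(pooled_labels.index[pooled_labels == "high"]))
    low = clin.subset(list(pooled_labels.index[pooled_labels == "low"]))

    analysis = CohortAnalysis(
        scores=scores,
        groups=groups,
        pooled_labels=pooled_labels,
        pooled_scores=pooled_scores,
        km_high=km_estimate(high),
        km_low=km_estimate(low),
        mantel_cox=logrank_test(low, high),
        wilcoxon=gehan_breslow_wilcoxon(low, high),
        hr_mantel_haenszel=hazard_ratio(low, high, "mantel_haenszel"),
        hr_logrank_oe=hazard_ratio(low, high, "logrank_oe"),
        cox=cox_ph(clin, pooled_scores.loc[clin.patient_ids].to_numpy()),
    )
    if mutation is not None:
        # associations are defined per expression cohort; pool labels
        merged_groups = GroupAssignment(
            list(pooled_labels.index),
            pooled_labels.to_numpy(),
            cluster_means={}, kmeans_inertia=float("nan"),
            seed=seed, n_init=n_init)
        merged_scores = ScoreTable(
            list(pooled_scores.index),
            raw_sum=pooled_scores.to_numpy(),
            score=pooled_scores.to_numpy(), cohort_label="pooled")
        analysis.associations = compare_exposures(mutation, merged_groups)
        analysis.neoantigen_regression = regress_neoantigens(
            mutation, merged_scores)
    return analysis


def write_provenance(path: str | Path, config: Mapping, seed: int,
                     counts: Mapping[str, int] | None = None) -> None:
    """Machine-readable provenance: config hash, seed, version, counts."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    record = {
        "package": "urosig",
        "version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": int(seed),
        "counts": dict(counts or {}),
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
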