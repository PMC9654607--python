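"""Tumour stratification: two-group k-means and heatmap leaf ordering.

Patients are embedded as points in signature-gene space (raw
log2(TPM+1) or array-intensity values, no standardisation) and split
by squared-Euclidean k-means with k = 2, k-means++ initialisation and
multiple restarts.  The cluster with the higher mean signature score
is labelled "high".  For heatmaps, genes and samples are ordered by
the leaf order of complete-linkage agglomerative clustering on
Euclidean distances.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .core_io import ExpressionMatrix
from .signature import ScoreTable

logger = logging.getLogger("urosig")

__all__ = ["GroupAssignment", "kmeans2", "hierarchical_order"]


@dataclass
class GroupAssignment:
    """High/low group labels with the clustering diagnostics."""

    patient_ids: list[str]
    labels: np.ndarray            # "high"/"low" per patient, input order
    cluster_means: dict[str, float]  # mean signature score per label
    kmeans_inertia: float
    seed: int
    n_init: int

    def series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.patient_ids, name="label")

    def ids_for(self, label: str) -> list[str]:
        return [p for p, l in zip(self.patient_ids, self.labels) if l == label]

    def to_frame(self, scores: ScoreTable | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"label": self.labels},
                          index=pd.Index(self.patient_ids, name="patient_id"))
        if scores is not None:
            df["score"] = scores.series().reindex(df.index)
        return df


def _derived_seed(seed: int, patient_ids: list[str]) -> int:
    """Restart-RNG seed from (seed, sorted patient IDs), not array order."""
    digest = zlib.crc32("|".join(sorted(patient_ids)).encode())
    return (int(seed) ^ digest) & 0x7FFFFFFF


def kmeans2(
    m: ExpressionMatrix,
    scores: ScoreTable,
    seed: int = 0,
    n_init: int = 50,
) -> GroupAssignment:
    """Two-group Euclidean k-means over signature-gene expression.

    ``m`` should already be restricted to the signature genes; columns
    are patients.  Clustering is performed on patients sorted by ID so
    the result is invariant to input column order; labels are returned
    in the input order.  Ties in mean score between the two clusters
    are broken by calling the cluster that contains the lowest input
    patient index "low".
    """
    ids = m.sample_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 patients")
    if set(ids) != set(scores.patient_ids):
        raise ValueError("matrix patients and score table patients differ")
    order = np.argsort(np.array(ids, dtype=object))
    sorted_ids = [ids[i] for i in order]
    x = m.data.to_numpy(float).T[order]
    if np.unique(x, axis=0).shape[0] < 2:
        raise ValueError("all patient feature vectors identical")

    km = KMeans(n_clusters=2, init="k-means++", n_init=n_init,
                random_state=_derived_seed(seed, ids))
    assign_sorted = km.fit_predict(x)
    if len(np.unique(assign_sorted)) < 2:
        raise RuntimeError("k-means produced an empty cluster")

    score_by_id = dict(zip(scores.patient_ids, np.asarray(scores.score, float)))
    cluster_of = dict(zip(sorted_ids, assign_sorted))
    assign = np.array([cluster_of[p] for p in ids])
    mean0 = float(np.mean([score_by_id[p] for p, c in zip(ids, assign) if c == 0]))
    mean1 = float(np.mean([score_by_id[p] for p, c in zip(ids, assign) if c == 1]))
    if mean0 == mean1:
        # deterministic tie-break: the cluster holding the lowest input
        # patient index is "low"
        low_cluster = assign[0]
    else:
        low_cluster = 0 if mean0 < mean1 else 1
    labels = np.where(assign == low_cluster, "low", "high")
    means = {
        "low": mean0 if low_cluster == 0 else mean1,
        "high": mean1 if low_cluster == 0 else mean0,
    }
    return GroupAssignment(ids, labels, means, float(km.inertia_),
                           int(seed), int(n_init))


def hierarchical_order(m: ExpressionMatrix, axis: str = "samples") -> list[str]:
    """Dendrogram leaf order from complete-linkage Euclidean clustering.

    ``axis`` selects whether genes (rows) or samples (columns) are
    ordered; the returned ID list is consumable by any heatmap tool.
    """
    if axis == "genes":
        x = m.data.to_numpy(float)
        ids = m.gene_ids
    elif axis == "samples":
        x = m.data.to_numpy(float).T
        ids = m.sample_ids
    else:
        raise ValueError("axis must be 'genes' or 'samples'")
    if len(ids) < 2:
        raise ValueError("need at least 2 items to order")
    link = hierarchy.linkage(pdist(x, metric="euclidean"), method="complete")
    return [ids[i] for i in hierarchy.leaves_list(link)]
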