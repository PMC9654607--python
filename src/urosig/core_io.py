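"""Shared data model and TSV I/O for the signature pipeline.

Every stage of the pipeline exchanges data through four table kinds:
gene-level expression matrices (genes as rows, samples as columns),
paired control/treated designs for the in vitro experiment, clinical
follow-up tables, and per-patient mutational-signature exposure tables.
All tables are tab-separated UTF-8 text with Unix newlines; values are
serialised with 6 significant digits and read back as doubles.

Gene identifiers are matched case-sensitively and exactly; duplicate
gene rows are an error, never aggregated.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("urosig")

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "PairedDesign",
    "ClinicalTable",
    "MutationTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_clinical",
    "write_clinical",
    "read_mutation_table",
    "write_mutation_table",
    "read_gene_list",
    "write_gene_list",
    "log2p1_transform",
]

SBS_COLUMNS = ("SBS2", "SBS13", "SBS4", "SBS5")


class Scale(str, Enum):
    """Measurement scale of an expression matrix."""

    TPM = "tpm"
    LOG2P1 = "log2p1"
    ARRAY = "array_intensity"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate {what}: {', '.join(dups)}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with an explicit scale.

    ``data`` holds genes as rows (index = gene IDs) and samples as
    columns.  TPM matrices must be non-negative; log2(TPM+1) and array
    intensities are unconstrained reals.
    """

    data: pd.DataFrame
    scale: Scale = Scale.TPM

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        _check_unique(list(self.data.index), "gene IDs")
        _check_unique(list(self.data.columns), "sample IDs")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.scale is Scale.TPM and np.nanmin(values, initial=0.0) < 0:
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative TPM at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes].copy(), self.scale)


@dataclass
class PairedDesign:
    """Donor -> (control sample, treated sample) mapping."""

    pairs: dict[str, tuple[str, str]]

    @property
    def donors(self) -> list[str]:
        return list(self.pairs)

    @property
    def n_donors(self) -> int:
        return len(self.pairs)

    def control_ids(self) -> list[str]:
        return [c for c, _ in self.pairs.values()]

    def treated_ids(self) -> list[str]:
        return [t for _, t in self.pairs.values()]

    def validate_against(self, m: ExpressionMatrix) -> None:
        """Every referenced sample must appear in ``m`` exactly once."""
        referenced = self.control_ids() + self.treated_ids()
        _check_unique(referenced, "design sample references")
        missing = [s for s in referenced if s not in m.data.columns]
        if missing:
            raise ValueError(f"design samples absent from matrix: {missing}")


@dataclass
class ClinicalTable:
    """Per-patient follow-up time (months) and event indicator.

    ``event`` is 1 for recurrence/death and 0 for censoring; the
    endpoint records whether times are recurrence-free or overall
    survival.  Rows with missing time or event are dropped at read time
    and counted in ``n_dropped``.
    """

    df: pd.DataFrame  # columns: time, event; index: patient_id
    endpoint: str = "RFS"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.endpoint not in ("RFS", "OS"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        _check_unique(list(self.df.index), "patient IDs")
        t = self.df["time"].to_numpy(float)
        e = self.df["event"].to_numpy(float)
        if np.any(t < 0):
            raise ValueError("negative follow-up time")
        if not np.all(np.isin(e, (0.0, 1.0))):
            bad = sorted(set(e) - {0.0, 1.0})
            raise ValueError(f"event indicator outside {{0,1}}: {bad}")
        self.df = self.df.assign(time=t, event=e.astype(int))

    @property
    def patient_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def time(self) -> np.ndarray:
        return self.df["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.df["event"].to_numpy(int)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, patient_ids: Iterable[str]) -> "ClinicalTable":
        ids = [p for p in patient_ids]
        missing = [p for p in ids if p not in self.df.index]
        if missing:
            raise KeyError(f"patients absent from clinical table: {missing}")
        return ClinicalTable(self.df.loc[ids].copy(), self.endpoint)


@dataclass
class MutationTable:
    """Per-patient mutational-signature exposures and neoantigen load.

    Exposures are attributed mutation counts for the APOBEC signatures
    SBS2/SBS13 and the non-APOBEC controls SBS4/SBS5; neoantigen_load
    is a non-negative integer count of predicted neoantigens.
    """

    df: pd.DataFrame  # columns: SBS2, SBS13, SBS4, SBS5, neoantigen_load

    def __post_init__(self) -> None:
        _check_unique(list(self.df.index), "patient IDs")
        for col in SBS_COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"missing exposure column {col}")
            if (self.df[col] < 0).any():
                raise ValueError(f"negative exposure in {col}")
        if "neoantigen_load" not in self.df.columns:
            raise ValueError("missing neoantigen_load column")
        load = self.df["neoantigen_load"]
        if (load < 0).any():
            raise ValueError("negative neoantigen_load")
        self.df = self.df.assign(neoantigen_load=load.astype(int))

    @property
    def patient_ids(self) -> list[str]:
        return list(self.df.index)


# ---------------------------------------------------------------------------
# readers / writers

_FLOAT_FMT = "%.6g"


def read_expression_matrix(path: str | Path, scale: Scale | str) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column ``gene_id``, header = sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    _check_unique(list(df.index), "gene IDs")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            raise ValueError(
                f"non-numeric cell in column {col!r}, gene(s) {list(bad[:5])}"
            )
    return ExpressionMatrix(df.astype(float), Scale(scale))


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id",
                  float_format=_FLOAT_FMT, lineterminator="\n")


def read_design(path: str | Path) -> PairedDesign:
    """Read a TSV with columns donor, control_sample, treated_sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"donor", "control_sample", "treated_sample"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table needs columns {sorted(required)}")
    _check_unique(list(df["donor"]), "donors")
    pairs = {
        r.donor: (r.control_sample, r.treated_sample) for r in df.itertuples()
    }
    return PairedDesign(pairs)


def write_design(design: PairedDesign, path: str | Path) -> None:
    rows = [
        {"donor": d, "control_sample": c, "treated_sample": t}
        for d, (c, t) in design.pairs.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_clinical(path: str | Path, endpoint: str = "RFS") -> ClinicalTable:
    """Read a TSV with columns patient_id, time, event.

    Rows with missing time or event are dropped (counted and logged);
    invalid values (negative time, event outside {0,1}) raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    for col in ("patient_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table needs column {col!r}")
    complete = df["time"].notna() & df["event"].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("read_clinical: dropped %d incomplete rows", n_dropped)
    df = df.loc[complete]
    table = ClinicalTable(
        df.set_index("patient_id")[["time", "event"]].astype(float),
        endpoint,
        n_dropped=n_dropped,
    )
    return table


def write_clinical(ct: ClinicalTable, path: str | Path) -> None:
    ct.df.to_csv(path, sep="\t", index_label="patient_id",
                 float_format=_FLOAT_FMT, lineterminator="\n")


def read_mutation_table(path: str | Path) -> MutationTable:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError("mutation table needs column 'patient_id'")
    return MutationTable(df.set_index("patient_id"))


def write_mutation_table(mt: MutationTable, path: str | Path) -> None:
    mt.df.to_csv(path, sep="\t", index_label="patient_id",
                 float_format=_FLOAT_FMT, lineterminator="\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read one gene symbol per line; '#' lines are comments.

    Returns the de-duplicated list preserving first occurrence; an
    empty file (no symbols) is an error.
    """
    out: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line not in seen:
            seen.add(line)
            out.append(line)
    if not out:
        raise ValueError(f"gene list {path} is empty")
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def log2p1_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform; refuses to double-transform."""
    if m.scale is not Scale.TPM:
        raise ValueError(f"log2p1_transform expects TPM input, got {m.scale.value}")
    return ExpressionMatrix(np.log2(m.data + 1.0), Scale.LOG2P1)
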