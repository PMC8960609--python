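"""Reading, writing, and quality control of expression/clinical/survival tables.

Formats
-------
Expression: tab-delimited, genes as rows, ``gene_id`` first column, one
column per sample.  Clinical and survival: CSV with named headers.

Quality control mirrors a standard two-rule gene filter (all-zero genes
and genes with excess missingness are removed) followed by restriction to
samples with complete clinical covariates present in every table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DataError,
    Dataset,
    ExpressionMatrix,
    SurvivalOutcome,
    validate_clinical,
)


def read_expression(path, unit: str) -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    Raises :class:`DataError` on ragged rows, duplicate gene/sample ids,
    or values violating the declared unit (e.g. fractional counts).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.columns[0] != "gene_id":
        raise DataError(f"{path}: first column must be 'gene_id', got {frame.columns[0]!r}")
    dup = frame["gene_id"][frame["gene_id"].duplicated()]
    if not dup.empty:
        raise DataError(f"{path}: duplicate gene rows: {dup.unique().tolist()}")
    data = frame.set_index("gene_id")
    data.index.name = None
    try:
        data = data.astype(float)
    except ValueError as exc:
        raise DataError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(data, unit)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.data.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"sample_id": str})
    return validate_clinical(frame)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    validate_clinical(clinical).to_csv(path, index=False)


def read_survival(path) -> SurvivalOutcome:
    return SurvivalOutcome.from_frame(pd.read_csv(path, dtype={"sample_id": str}))


def write_survival(outcome: SurvivalOutcome, path) -> None:
    outcome.to_frame().to_csv(path, index=False)


@dataclass
class GeneRemovalReport:
    """Per-gene record of why QC removed it."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    def add(self, gene_id: str, reason: str) -> None:
        self.removed.append((gene_id, reason))

    @property
    def removed_ids(self) -> list[str]:
        return [g for g, _ in self.removed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["gene_id", "reason"])


def qc_filter_genes(
    matrix: ExpressionMatrix, max_missing: float = 0.10
) -> tuple[ExpressionMatrix, GeneRemovalReport]:
    """Drop genes that are all zero or have missingness strictly above threshold.

    A gene with missing proportion exactly equal to ``max_missing`` is kept
    (the removal rule is a strict inequality).  Returns the filtered matrix
    and a report naming each removed gene with its reason.
    """
    values = matrix.values()
    report = GeneRemovalReport()
    missing_prop = np.isnan(values).mean(axis=1)
    observed_all_zero = np.nansum(np.abs(values), axis=1) == 0
    keep = []
    for i, gene in enumerate(matrix.gene_ids):
        if observed_all_zero[i]:
            report.add(gene, "all_zero")
        elif missing_prop[i] > max_missing:
            report.add(gene, f"missing_{missing_prop[i]:.3f}>{max_missing}")
        else:
            keep.append(gene)
    if not keep:
        raise DataError("no genes remain after QC filtering")
    return matrix.subset_genes(keep), report


def qc_filter_samples(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    outcome: SurvivalOutcome,
    counts: ExpressionMatrix | None = None,
) -> Dataset:
    """Restrict to samples present in every table with complete covariates.

    Sample order in every returned table is the sorted id intersection, so
    repeated runs produce identical alignment.  Raises on an empty
    intersection.
    """
    validate_clinical(clinical)
    complete = clinical.dropna(subset=[c for c in clinical.columns if c != "sample_id"])
    ids = set(matrix.sample_ids) & set(complete["sample_id"]) & set(outcome.sample_ids)
    if counts is not None:
        ids &= set(counts.sample_ids)
    if not ids:
        raise DataError("no samples shared by expression, clinical, and survival tables")
    order = sorted(ids)
    clin = (
        complete[complete["sample_id"].isin(ids)]
        .set_index("sample_id")
        .loc[order]
        .reset_index()
    )
    return Dataset(
        fpkm=matrix.subset_samples(order),
        clinical=clin,
        survival=outcome.subset(order),
        counts=counts.subset_samples(order) if counts is not None else None,
    )


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1), tagging the result as ``log2``."""
    if matrix.unit == "log2":
        raise DataError("matrix is already log2-transformed")
    values = matrix.values()
    if np.nanmin(values) < 0:
        raise DataError("cannot log-transform negative values")
    return ExpressionMatrix(
        pd.DataFrame(
            np.log2(values + 1.0), index=matrix.data.index, columns=matrix.data.columns
        ),
        "log2",
    )


def read_dataset_dir(path) -> Dataset:
    """Load a dataset directory written by the simulator or the CLI."""
    path = Path(path)
    fpkm = read_expression(path / "fpkm.tsv", "fpkm")
    counts_path = path / "counts.tsv"
    counts = read_expression(counts_path, "counts") if counts_path.exists() else None
    clinical = read_clinical(path / "clinical.csv")
    outcome = read_survival(path / "survival.csv")
    ids = fpkm.sample_ids
    clinical = clinical.set_index("sample_id").loc[ids].reset_index()
    return Dataset(
        fpkm=fpkm, clinical=clinical, survival=outcome.subset(ids), counts=counts
    )


def write_dataset_dir(dataset: Dataset, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_expression(dataset.fpkm, path / "fpkm.tsv")
    if dataset.counts is not None:
        write_expression(dataset.counts, path / "counts.tsv")
    write_clinical(dataset.clinical, path / "clinical.csv")
    write_survival(dataset.survival, path / "survival.csv")
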