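"""Core containers shared by every stage of the two-phase pipeline.

The pipeline moves three objects around: an expression matrix
(genes x samples, tagged with its unit), a clinical covariate table,
and right-censored survival outcomes.  All three are thin, validated
wrappers over pandas structures so that downstream stages can rely on
aligned ids without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed unit tags for an expression matrix.
EXPRESSION_UNITS = ("counts", "fpkm", "log2", "cpm")

#: Clinical covariate columns required for the survival models.
CLINICAL_COLUMNS = (
    "sample_id",
    "age",
    "gender",
    "race",
    "smoke_status",
    "pack_years",
    "clinical_stage",
    "histology",
)


class DataError(ValueError):
    """Raised when an input table violates its structural contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a unit tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample id.
    unit
        One of ``counts`` (non-negative integers), ``fpkm`` (non-negative
        reals), ``cpm`` (library-normalized reals) or ``log2``
        (log2-transformed values, may be any real).
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise DataError(f"unknown expression unit {self.unit!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if self.unit == "counts":
            if (finite < 0).any():
                raise DataError("counts matrix contains negative values")
            if not np.allclose(finite, np.round(finite)):
                bad = finite[~np.isclose(finite, np.round(finite))][:3]
                raise DataError(f"counts matrix contains non-integers, e.g. {bad}")
        elif self.unit in ("fpkm", "cpm") and (finite < 0).any():
            raise DataError(f"{self.unit} matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        """Genes x samples float array."""
        return self.data.to_numpy(dtype=float)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise DataError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.unit)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(sample_ids)], self.unit)


@dataclass
class SurvivalOutcome:
    """Right-censored outcomes: observed time (years) and event indicator."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise DataError("duplicate sample ids in survival outcome")
        if not (len(self.sample_ids) == self.time.size == self.event.size):
            raise DataError("survival outcome fields have inconsistent lengths")
        if (self.time <= 0).any():
            raise DataError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise DataError("event indicator must be 0/1")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def censoring_rate(self) -> float:
        return float(1.0 - self.event.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurvivalOutcome":
        required = {"sample_id", "time", "event"}
        if not required.issubset(frame.columns):
            raise DataError(f"survival table needs columns {sorted(required)}")
        return cls(
            frame["sample_id"].astype(str).tolist(),
            frame["time"].to_numpy(dtype=float),
            frame["event"].to_numpy(dtype=int),
        )

    def subset(self, sample_ids) -> "SurvivalOutcome":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise DataError(f"sample absent from survival outcome: {exc}") from exc
        return SurvivalOutcome(list(sample_ids), self.time[rows], self.event[rows])


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical covariate table contract and return it unchanged."""
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing_cols:
        raise DataError(f"clinical table missing columns {missing_cols}")
    if clinical["sample_id"].duplicated().any():
        raise DataError("duplicate sample ids in clinical table")
    hist = clinical["histology"].dropna()
    bad = set(hist.unique()) - {"LUAD", "LUSC"}
    if bad:
        raise DataError(f"histology values outside {{LUAD, LUSC}}: {sorted(bad)}")
    return clinical


@dataclass
class Dataset:
    """One phase's aligned inputs: expression (two units), clinical, survival."""

    fpkm: ExpressionMatrix
    clinical: pd.DataFrame
    survival: SurvivalOutcome
    counts: ExpressionMatrix | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        ids = self.fpkm.sample_ids
        if self.clinical["sample_id"].tolist() != ids:
            raise DataError("clinical table not sample-aligned with expression")
        if self.survival.sample_ids != ids:
            raise DataError("survival outcome not sample-aligned with expression")
        if self.counts is not None and self.counts.sample_ids != ids:
            raise DataError("counts matrix not sample-aligned with expression")

    @property
    def sample_ids(self) -> list[str]:
        return self.fpkm.sample_ids
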