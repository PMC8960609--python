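"""Covariate design-matrix construction for forests and Cox models.

Continuous covariates (age, pack-years) enter as-is; categorical
covariates are reference-coded with the most frequent level as reference
(ties broken alphabetically) so the encoding is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CONTINUOUS_COVARIATES = ("age", "pack_years")
CATEGORICAL_COVARIATES = ("gender", "race", "smoke_status", "clinical_stage", "histology")


def encode_covariates(
    clinical: pd.DataFrame, exclude: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Build a numeric covariate design matrix from a clinical table.

    Returns a DataFrame (samples x encoded covariates) whose row order
    matches the clinical table.  ``exclude`` drops covariates entirely
    (used e.g. when stratifying by histology).  Single-level categorical
    covariates are dropped (they would be constant columns).
    """
    columns: dict[str, np.ndarray] = {}
    for cov in CONTINUOUS_COVARIATES:
        if cov in exclude or cov not in clinical.columns:
            continue
        columns[cov] = clinical[cov].to_numpy(dtype=float)
    for cov in CATEGORICAL_COVARIATES:
        if cov in exclude or cov not in clinical.columns:
            continue
        series = clinical[cov].astype(str)
        counts = series.value_counts()
        # most frequent level is the reference; alphabetical tie-break
        top = counts.max()
        reference = sorted(counts[counts == top].index)[0]
        for level in sorted(series.unique()):
            if level == reference:
                continue
            columns[f"{cov}_{level}"] = (series == level).to_numpy(dtype=float)
    design = pd.DataFrame(columns, index=clinical.index)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    return design.drop(columns=constant)
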