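"""Variable-importance ranking and sliding-window sequential forward selection.

The screening stage ranks genes by permutation variable importance from
a covariate-forced survival forest, then adds them one at a time in rank
order, refitting the forest on the top-k genes (plus all covariates) and
recording the OOB error.  The error-versus-k curve is smoothed with a
centered moving average and the k minimizing the smoothed error (smallest
k on ties) defines the candidate gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import SurvivalOutcome
from .forest import (
    SurvivalForest,
    SurvivalForestConfig,
    fit_survival_forest,
    oob_error,
    variable_importance,
)

DEFAULT_K_MAX = 50


@dataclass
class VISRanking:
    """Genes ordered by descending variable importance (ties broken by id)."""

    table: pd.DataFrame  # columns: gene_id, importance

    def __post_init__(self) -> None:
        imp = self.table["importance"].to_numpy()
        if not (np.diff(imp) <= 1e-15).all():
            raise ValueError("importance column is not descending")

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class OOBCurve:
    """Raw and smoothed OOB error per model size k, plus the selected k."""

    k: np.ndarray
    oob: np.ndarray
    smoothed: np.ndarray
    selected_k: int
    window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "oob_error": self.oob, "smoothed_error": self.smoothed}
        )


def rank_genes(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: SurvivalOutcome,
    config: SurvivalForestConfig,
) -> tuple[VISRanking, SurvivalForest]:
    """Fit the full-feature forest and rank genes by permutation importance."""
    forest = fit_survival_forest(features, covariates, outcome, config)
    importance = variable_importance(forest)
    table = (
        importance.rename("importance")
        .rename_axis("gene_id")
        .reset_index()
        .sort_values(["importance", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return VISRanking(table), forest


def smooth_curve(errors: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated at the boundaries."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    half = window // 2
    out = np.empty_like(errors, dtype=float)
    for i in range(errors.size):
        lo, hi = max(0, i - half), min(errors.size, i + half + 1)
        out[i] = errors[lo:hi].mean()
    return out


def select_minimum(smoothed: np.ndarray) -> int:
    """1-based k attaining the minimum smoothed error; smallest k on ties."""
    return int(np.argmin(smoothed)) + 1


def swsfs_select(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: SurvivalOutcome,
    ranking: VISRanking,
    config: SurvivalForestConfig,
    window: int = 5,
    k_max: int | None = None,
) -> tuple[list[str], OOBCurve]:
    """Sequential forward selection over the importance ranking.

    For k = 1..k_max a forest on the top-k genes (plus all covariates) is
    fitted and its OOB error recorded; the candidate set is the top
    ``selected_k`` genes at the smoothed-error minimum.  Each k uses a
    seed derived from the base seed and k, so the procedure is
    deterministic given (data, seed, window).
    """
    if len(ranking) == 0:
        raise ValueError("empty importance ranking")
    k_max = min(k_max or DEFAULT_K_MAX, len(ranking))
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    errors = np.empty(k_max)
    for k in range(1, k_max + 1):
        genes = ranking.top(k)
        sub_config = replace(
            config,
            seed=int(np.random.SeedSequence([config.seed, 15485863, k]).generate_state(1)[0] % (2**31)),
            mtry=min(
                config.resolve_mtry(len(ranking)) if config.mtry == "sqrt" else int(config.mtry),
                k,
            ),
        )
        forest_k = fit_survival_forest(
            features[genes], covariates, outcome, sub_config
        )
        errors[k - 1] = oob_error(forest_k)
    smoothed = smooth_curve(errors, window)
    selected_k = select_minimum(smoothed)
    curve = OOBCurve(
        k=np.arange(1, k_max + 1),
        oob=errors,
        smoothed=smoothed,
        selected_k=selected_k,
        window=window,
    )
    return ranking.top(selected_k), curve
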