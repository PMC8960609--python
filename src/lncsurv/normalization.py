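"""Trimmed mean of M-values (TMM) scaling factors for count libraries.

Between-sample normalization for RNA-seq counts: each library is
compared with a reference library through per-gene log-ratios (M) and
average log-abundances (A); after double-trimming (30% on M, 5% on A)
the surviving M values are combined by a precision-weighted mean whose
weights come from the binomial delta-method variance approximation, and
the scaling factor is 2 to that mean.  Factors are rescaled to have
geometric mean 1 across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DataError, ExpressionMatrix


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors (geometric mean 1) and the reference id."""

    factors: pd.Series  # index = sample_id
    reference_sample_id: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise DataError("TMM factors must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.factors.index, "factor": self.factors.to_numpy()}
        )


def _upper_quartile(column: np.ndarray, lib_size: float) -> float:
    """75th percentile of nonzero relative abundances of one library."""
    nonzero = column[column > 0]
    if nonzero.size == 0:
        raise DataError("zero-count library")
    return float(np.quantile(nonzero / lib_size, 0.75))


def _pair_tmm(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Log2 TMM factor of one library against the reference."""
    shared = (obs > 0) & (ref > 0)
    if not shared.any():
        raise DataError("library shares no expressed genes with the reference")
    o, r = obs[shared], ref[shared]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    # ranks are 1-based; average ranks for ties keep the rule symmetric
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    # guard against numerically tiny factors from symmetric trimming
    return 0.0 if abs(f) < 1e-10 else f


def tmm_factors(
    counts: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """TMM scaling factor per sample.

    The reference library is the sample whose upper quartile of nonzero
    relative abundances is closest to the mean upper quartile across
    samples (ties broken by lexicographically smallest sample id).

    Raises :class:`DataError` on matrices with fewer than two samples,
    zero-count libraries, or a library sharing no expressed genes with
    the reference.
    """
    if counts.unit != "counts":
        raise DataError("TMM requires a counts matrix")
    if counts.n_samples < 2:
        raise DataError("TMM requires at least two samples")
    values = counts.values()
    if np.isnan(values).any():
        raise DataError("TMM requires complete counts (no missing values)")
    lib_sizes = values.sum(axis=0)
    if (lib_sizes <= 0).any():
        raise DataError("zero-count library")
    samples = counts.sample_ids

    uq = np.array([_upper_quartile(values[:, j], lib_sizes[j]) for j in range(len(samples))])
    dist = np.abs(uq - uq.mean())
    best = dist.min()
    ref_idx = min(
        (j for j in range(len(samples)) if dist[j] == best), key=lambda j: samples[j]
    )
    ref = values[:, ref_idx]
    n_ref = lib_sizes[ref_idx]

    log_factors = np.zeros(len(samples))
    for j in range(len(samples)):
        if j == ref_idx:
            continue
        log_factors[j] = _pair_tmm(values[:, j], ref, lib_sizes[j], n_ref, trim_m, trim_a)
    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return NormalizationFactors(
        factors=pd.Series(factors, index=samples), reference_sample_id=samples[ref_idx]
    )


def apply_factors(
    counts: ExpressionMatrix, factors: NormalizationFactors
) -> ExpressionMatrix:
    """Counts -> CPM-like values on effective library sizes (total x factor)."""
    missing = [s for s in counts.sample_ids if s not in factors.factors.index]
    if missing:
        raise DataError(f"missing TMM factor for samples: {missing[:5]}")
    values = counts.values()
    lib_sizes = values.sum(axis=0)
    f = factors.factors.loc[counts.sample_ids].to_numpy()
    normalized = values / (lib_sizes * f) * 1e6
    return ExpressionMatrix(
        pd.DataFrame(normalized, index=counts.data.index, columns=counts.data.columns),
        "cpm",
    )
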