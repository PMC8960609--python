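"""Trans-platform pseudo-validation via surrogate genes.

Discovery hits whose genes are not measured on the validation platform
are validated through surrogates: for each missing target, the gene
measured on both platforms with the maximum, FDR-significant absolute
correlation with the target in the DISCOVERY data (the only dataset
where both are observed) stands in for it.  The main-effect or
interaction model is refitted on the validation cohort with the
surrogate expressions, and a term passes validation iff its focal p is
at most 0.05 and the focal effect direction agrees with discovery.

Histology-stratified refits (LUAD-only / LUSC-only) check whether an
effect is carried by one subtype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult, bh_fdr, interaction_scan, main_effect_scan
from .datatypes import DataError, Dataset, ExpressionMatrix, SurvivalOutcome
from .design import encode_covariates


@dataclass
class SurrogateEntry:
    target: str
    surrogate: str | None
    r: float
    p: float
    q: float
    is_identity: bool

    @property
    def resolvable(self) -> bool:
        return self.surrogate is not None


@dataclass
class SurrogateMap:
    """target gene -> validation-platform surrogate with its correlation."""

    entries: dict[str, SurrogateEntry]

    def __getitem__(self, target: str) -> SurrogateEntry:
        return self.entries[target]

    def resolve(self, target: str) -> str | None:
        entry = self.entries.get(target)
        return entry.surrogate if entry else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target": e.target,
                    "surrogate": e.surrogate,
                    "r": e.r,
                    "p": e.p,
                    "q": e.q,
                    "is_identity": e.is_identity,
                }
                for e in self.entries.values()
            ]
        )


def _correlations(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of x against each row of Y."""
    n = x.size
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((Yc @ xc) / denom, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = np.finfo(float).tiny
    return r, p


def find_surrogates(
    targets: list[str],
    discovery_expr: ExpressionMatrix,
    validation_gene_set: list[str],
    q_threshold: float = 0.05,
    method: str = "pearson",
) -> SurrogateMap:
    """Pick each target's surrogate on the validation platform.

    Targets measured on the validation platform map to themselves
    (identity surrogate, r = 1).  Otherwise the surrogate is the shared
    gene with maximum |r| among those whose correlation FDR-q (BH within
    the target's candidate family) is at most ``q_threshold``; |r| ties
    break to the smallest gene id.  A target with no eligible candidate
    is recorded as unresolvable.
    """
    if not validation_gene_set:
        raise DataError("validation gene set is empty")
    shared = [g for g in discovery_expr.gene_ids if g in set(validation_gene_set)]
    log_expr = np.log2(discovery_expr.values() + 1.0)
    row_of = {g: i for i, g in enumerate(discovery_expr.gene_ids)}
    entries: dict[str, SurrogateEntry] = {}
    for target in targets:
        if target not in row_of:
            raise DataError(f"target {target!r} absent from discovery expression")
        if target in set(validation_gene_set):
            entries[target] = SurrogateEntry(target, target, 1.0, 0.0, 0.0, True)
            continue
        candidates = [g for g in shared if g != target]
        if not candidates:
            entries[target] = SurrogateEntry(target, None, np.nan, np.nan, np.nan, False)
            continue
        x = log_expr[row_of[target]]
        if np.ptp(x) == 0:
            raise DataError(f"target {target!r} has zero variance")
        Y = log_expr[[row_of[g] for g in candidates]]
        keep = np.ptp(Y, axis=1) > 0
        candidates = [g for g, k in zip(candidates, keep) if k]
        if method == "pearson":
            r, p = _correlations(x, Y[keep])
        elif method == "spearman":
            xr = stats.rankdata(x)
            Yr = np.apply_along_axis(stats.rankdata, 1, Y[keep])
            r, p = _correlations(xr, Yr)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
        q = bh_fdr(np.maximum(p, np.finfo(float).tiny))
        eligible = np.nonzero(q <= q_threshold)[0]
        if eligible.size == 0:
            entries[target] = SurrogateEntry(target, None, np.nan, np.nan, np.nan, False)
            continue
        best_abs = np.max(np.abs(r[eligible]))
        tied = [i for i in eligible if np.abs(r[i]) == best_abs]
        best = min(tied, key=lambda i: candidates[i])
        entries[target] = SurrogateEntry(
            target, candidates[best], float(r[best]), float(p[best]), float(q[best]), False
        )
    return SurrogateMap(entries)


@dataclass
class ValidationVerdict:
    """Outcome of re-testing one discovery hit on the validation cohort."""

    term: str
    analysis_type: str
    discovery: AssociationResult
    validation: AssociationResult | None
    surrogates: dict[str, str | None]
    passed: bool
    reasons: list[str]

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "analysis_type": self.analysis_type,
            "passed": self.passed,
            "reasons": "; ".join(self.reasons) or "validated",
            "surrogates": ",".join(f"{k}->{v}" for k, v in self.surrogates.items()),
            "discovery_hr": self.discovery.hr,
            "discovery_p": self.discovery.p,
            "validation_hr": self.validation.hr if self.validation else np.nan,
            "validation_p": self.validation.p if self.validation else np.nan,
        }


def validate_terms(
    discovery_results: list[AssociationResult],
    surrogate_map: SurrogateMap,
    validation: Dataset,
    p_threshold: float = 0.05,
    transform: bool = True,
) -> list[ValidationVerdict]:
    """Refit each retained discovery term on the validation cohort.

    A verdict passes iff (1) the focal-term validation p <= ``p_threshold``
    and (2) the focal log-HR has the same sign in both phases.  Both
    criteria apply to the focal term only (the gene for a main effect,
    the product for an interaction).
    """
    from .io import log_transform

    expr = log_transform(validation.fpkm) if transform else validation.fpkm
    covariates = encode_covariates(validation.clinical)
    verdicts = []
    for res in discovery_results:
        surrogates = {g: surrogate_map.resolve(g) for g in res.genes}
        reasons: list[str] = []
        if any(s is None for s in surrogates.values()):
            missing = [g for g, s in surrogates.items() if s is None]
            verdicts.append(
                ValidationVerdict(
                    res.term, res.analysis_type, res, None, surrogates, False,
                    [f"no eligible surrogate for {g}" for g in missing],
                )
            )
            continue
        sub = list(dict.fromkeys(surrogates.values()))  # unique, order-stable
        try:
            if res.analysis_type == "main":
                scan = main_effect_scan(
                    expr, sub[:1], covariates, validation.survival, phase="validation"
                )
            else:
                if len(sub) < 2:
                    raise DataError(
                        "interaction surrogates collapse to a single gene"
                    )
                scan = interaction_scan(
                    expr, sub[:2], covariates, validation.survival, phase="validation"
                )
            val = scan[0]
        except DataError as exc:
            verdicts.append(
                ValidationVerdict(
                    res.term, res.analysis_type, res, None, surrogates, False,
                    [f"validation fit failed: {exc}"],
                )
            )
            continue
        if not val.ok:
            reasons.append(f"validation fit failure: {val.error}")
        else:
            if not val.p <= p_threshold:
                reasons.append(f"validation p > {p_threshold}")
            if val.direction != res.direction:
                reasons.append("direction flip")
        verdicts.append(
            ValidationVerdict(
                res.term, res.analysis_type, res, val, surrogates, not reasons, reasons
            )
        )
    return verdicts


def stratified_analysis(
    results: list[AssociationResult],
    dataset: Dataset,
    transform: bool = True,
    min_events_per_coef: int = 10,
) -> pd.DataFrame:
    """Refit each focal model within LUAD-only and LUSC-only subsets.

    Histology is dropped from the covariates inside a stratum; fits with
    fewer than ``min_events_per_coef`` events per coefficient are flagged
    unstable.  Returns a tidy table of per-stratum focal estimates.
    """
    from .io import log_transform

    expr_all = log_transform(dataset.fpkm) if transform else dataset.fpkm
    rows = []
    for stratum in ("LUAD", "LUSC"):
        mask = dataset.clinical["histology"] == stratum
        ids = dataset.clinical.loc[mask, "sample_id"].tolist()
        if not ids:
            raise DataError(f"empty histology stratum {stratum}")
        expr = expr_all.subset_samples(ids)
        clinical = dataset.clinical[mask].reset_index(drop=True)
        outcome = dataset.survival.subset(ids)
        covariates = encode_covariates(clinical, exclude=("histology",))
        for res in results:
            n_coef = len(res.genes) + (1 if res.analysis_type == "interaction" else 0)
            n_coef += covariates.shape[1]
            try:
                if res.analysis_type == "main":
                    sub = main_effect_scan(
                        expr, list(res.genes), covariates, outcome, phase=stratum
                    )[0]
                else:
                    sub = interaction_scan(
                        expr, list(res.genes), covariates, outcome, phase=stratum
                    )[0]
                rows.append(
                    {
                        "term": res.term,
                        "analysis_type": res.analysis_type,
                        "stratum": stratum,
                        "n": sub.n,
                        "n_events": sub.n_events,
                        "hr": sub.hr,
                        "ci_low": sub.ci_low,
                        "ci_high": sub.ci_high,
                        "p": sub.p,
                        "unstable": sub.n_events < min_events_per_coef * n_coef,
                        "error": sub.error,
                    }
                )
            except DataError as exc:
                rows.append(
                    {
                        "term": res.term,
                        "analysis_type": res.analysis_type,
                        "stratum": stratum,
                        "n": len(ids),
                        "n_events": int(outcome.n_events),
                        "hr": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                        "unstable": True,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)
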