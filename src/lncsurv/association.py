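"""Main-effect and pairwise-interaction Cox scans with FDR control.

Two model forms are scanned over a candidate gene set, always adjusted
for the clinical covariates:

* main effect:   h(t) = h0(t) exp(a1*gene + sum_i b_i*cov_i)
* interaction:   h(t) = h0(t) exp(a1*g1 + a2*g2 + a3*g1*g2 + sum_i b_i*cov_i)

The focal term is the gene coefficient (a1) for main effects and the
product coefficient (a3) for interactions.  Benjamini–Hochberg FDR is
applied separately within each scan family.  A sensitivity intersection
retains terms significant, with consistent direction, in both the
FPKM-based and TMM-based branches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cox import CoxError, CoxFit, cox_fit
from .datatypes import DataError, ExpressionMatrix, SurvivalOutcome


@dataclass
class AssociationResult:
    """One tested term (a gene's main effect or a gene pair's interaction)."""

    analysis_type: str  # "main" | "interaction"
    genes: tuple[str, ...]
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    phase: str
    n: int
    n_events: int
    converged: bool
    error: str | None = None
    fit: CoxFit | None = None

    @property
    def term(self) -> str:
        return ":".join(self.genes)

    @property
    def direction(self) -> int:
        """Sign of the focal log-hazard coefficient."""
        return int(np.sign(self.coef))

    @property
    def ok(self) -> bool:
        return self.error is None and self.converged


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _failed_result(analysis_type, genes, phase, n, n_events, message) -> AssociationResult:
    return AssociationResult(
        analysis_type=analysis_type,
        genes=genes,
        coef=np.nan,
        hr=np.nan,
        ci_low=np.nan,
        ci_high=np.nan,
        p=np.nan,
        q=np.nan,
        phase=phase,
        n=n,
        n_events=n_events,
        converged=False,
        error=message,
    )


def _focal_result(
    fit: CoxFit, focal: str, analysis_type: str, genes: tuple[str, ...], phase: str
) -> AssociationResult:
    j = fit.term_index(focal)
    return AssociationResult(
        analysis_type=analysis_type,
        genes=genes,
        coef=float(fit.coef[j]),
        hr=float(fit.hr[j]),
        ci_low=float(fit.ci_low[j]),
        ci_high=float(fit.ci_high[j]),
        p=float(fit.p[j]),
        q=np.nan,
        phase=phase,
        n=fit.n,
        n_events=fit.n_events,
        converged=fit.converged,
        fit=fit,
    )


def _apply_family_fdr(results: list[AssociationResult]) -> list[AssociationResult]:
    ok = [r for r in results if r.ok and np.isfinite(r.p)]
    if ok:
        qs = bh_fdr([max(r.p, np.nextafter(0, 1)) for r in ok])
        for r, q in zip(ok, qs):
            r.q = float(q)
    return results


def _gene_vector(expr: ExpressionMatrix, gene: str) -> np.ndarray:
    if gene not in expr.data.index:
        raise DataError(f"candidate gene {gene!r} absent from expression matrix")
    return expr.data.loc[gene].to_numpy(dtype=float)


def main_effect_scan(
    expr: ExpressionMatrix,
    candidates: list[str],
    covariates: pd.DataFrame,
    outcome: SurvivalOutcome,
    phase: str = "discovery",
) -> list[AssociationResult]:
    """One covariate-adjusted Cox fit per candidate gene; BH-FDR across the scan.

    Per-gene fit failures are recorded in the result (``error`` set) and the
    scan continues; failed fits take no part in the FDR family.
    """
    results = []
    cov = covariates.to_numpy(dtype=float)
    cov_names = [str(c) for c in covariates.columns]
    for gene in candidates:
        genes = (gene,)
        try:
            x = _gene_vector(expr, gene)
            X = np.column_stack([x, cov])
            fit = cox_fit(X, outcome.time, outcome.event, terms=[gene] + cov_names, warn=False)
            if not fit.converged or gene in fit.monotone_terms:
                reason = "non-convergence" if not fit.converged else "monotone focal term"
                results.append(
                    _failed_result("main", genes, phase, fit.n, fit.n_events, reason)
                )
                continue
            results.append(_focal_result(fit, gene, "main", genes, phase))
        except (CoxError, DataError) as exc:
            results.append(
                _failed_result("main", genes, phase, outcome.n, outcome.n_events, str(exc))
            )
    return _apply_family_fdr(results)


def interaction_scan(
    expr: ExpressionMatrix,
    candidates: list[str],
    covariates: pd.DataFrame,
    outcome: SurvivalOutcome,
    phase: str = "discovery",
) -> list[AssociationResult]:
    """Fit g1 + g2 + g1*g2 + covariates for every unordered candidate pair.

    The focal term is the product; BH-FDR spans all C(k, 2) pairs.
    """
    if len(candidates) < 2:
        raise ValueError("interaction scan needs at least two candidate genes")
    cov = covariates.to_numpy(dtype=float)
    cov_names = [str(c) for c in covariates.columns]
    results = []
    for g1, g2 in itertools.combinations(candidates, 2):
        genes = (g1, g2)
        term = f"{g1}:{g2}"
        try:
            x1, x2 = _gene_vector(expr, g1), _gene_vector(expr, g2)
            X = np.column_stack([x1, x2, x1 * x2, cov])
            fit = cox_fit(
                X, outcome.time, outcome.event,
                terms=[g1, g2, term] + cov_names, warn=False,
            )
            if not fit.converged or term in fit.monotone_terms:
                reason = "non-convergence" if not fit.converged else "monotone focal term"
                results.append(
                    _failed_result(
                        "interaction", genes, phase, fit.n, fit.n_events, reason
                    )
                )
                continue
            results.append(_focal_result(fit, term, "interaction", genes, phase))
        except (CoxError, DataError) as exc:
            results.append(
                _failed_result(
                    "interaction", genes, phase, outcome.n, outcome.n_events, str(exc)
                )
            )
    return _apply_family_fdr(results)


def sensitivity_intersection(
    results_fpkm: list[AssociationResult],
    results_tmm: list[AssociationResult],
    q_threshold: float = 0.05,
    require_direction: bool = True,
) -> tuple[list[AssociationResult], pd.DataFrame]:
    """Retain terms significant in BOTH normalization branches.

    A term passes iff its FDR-q <= ``q_threshold`` in both the FPKM and TMM
    result sets and (by default) the focal coefficient has the same sign in
    both.  Terms present in only one branch are excluded and logged in the
    returned report.  The retained results carry the FPKM-branch estimates.
    """
    by_term_tmm = {r.term: r for r in results_tmm}
    retained = []
    log = []
    for r in results_fpkm:
        partner = by_term_tmm.get(r.term)
        if partner is None:
            log.append((r.term, np.nan, np.nan, "absent from TMM branch"))
            continue
        if not (r.ok and partner.ok):
            log.append((r.term, r.q, partner.q, "fit failure in a branch"))
            continue
        if not (r.q <= q_threshold and partner.q <= q_threshold):
            log.append((r.term, r.q, partner.q, "not significant in both branches"))
            continue
        if require_direction and r.direction != partner.direction:
            log.append((r.term, r.q, partner.q, "direction disagreement"))
            continue
        retained.append(r)
        log.append((r.term, r.q, partner.q, "retained"))
    seen = {r.term for r in results_fpkm}
    for r in results_tmm:
        if r.term not in seen:
            log.append((r.term, np.nan, r.q, "absent from FPKM branch"))
    report = pd.DataFrame(log, columns=["term", "q_fpkm", "q_tmm", "status"])
    return retained, report


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten scan results to the CSV layout used by the CLI and drivers."""
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "analysis_type": [r.analysis_type for r in results],
            "phase": [r.phase for r in results],
            "hr": [r.hr for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "direction": [r.direction if r.ok else 0 for r in results],
            "n": [r.n for r in results],
            "n_events": [r.n_events for r in results],
            "converged": [r.converged for r in results],
            "error": [r.error for r in results],
        }
    )
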