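"""Risk-model comparison by time-dependent ROC/AUC, plus KM group analyses.

The basic model contains only clinical covariates; the optimized model
adds selected genes.  Discrimination at a horizon is measured with the
cumulative-case / dynamic-control time-dependent ROC, estimated with
the Kaplan–Meier weighting of Heagerty, Lumley & Pepe: cases are events
by the horizon, controls are subjects surviving past it, and censoring
enters through conditional KM estimates of S(horizon) within the
score-defined groups.  AUC differences between the two models get
percentile bootstrap confidence intervals and p-values, with both models
refitted inside every bootstrap replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test

from .cox import CoxError, CoxFit, cox_fit
from .datatypes import DataError, SurvivalOutcome


@dataclass
class RiskModel:
    """A Cox risk score over a fixed term list (covariates +/- genes)."""

    kind: str  # "basic" | "optimized"
    terms: list[str]
    fit: CoxFit | None = None

    def fitted(
        self, design: pd.DataFrame, outcome: SurvivalOutcome, drop_constant: bool = True
    ) -> "RiskModel":
        missing = [t for t in self.terms if t not in design.columns]
        if missing:
            raise DataError(f"design lacks model terms: {missing}")
        terms = list(self.terms)
        if drop_constant:
            # a term constant in this (re)sample is inestimable and only
            # shifts the linear predictor, leaving risk ranks and AUC
            # unchanged; dropping it keeps bootstrap replicates fittable
            # when a rare indicator level vanishes from the resample
            sub = design[terms].to_numpy(dtype=float)
            keep = (sub.max(axis=0) - sub.min(axis=0)) > 0
            terms = [t for t, k in zip(terms, keep) if k]
            if not terms:
                raise CoxError("all model terms constant in this sample")
        fit = cox_fit(design[terms], outcome.time, outcome.event, warn=False)
        return RiskModel(self.kind, terms, fit)


def risk_score(model: RiskModel, design: pd.DataFrame) -> np.ndarray:
    """Linear predictor sum(coef * term); higher = higher hazard."""
    if model.fit is None:
        raise DataError("risk model is not fitted")
    missing = [t for t in model.terms if t not in design.columns]
    if missing:
        raise DataError(f"design lacks model terms: {missing}")
    return design[model.terms].to_numpy(dtype=float) @ model.fit.coef


def _km_at_horizon(member: np.ndarray, order_time, order_event, horizon) -> np.ndarray:
    """KM survival at the horizon within each row's member subset.

    ``member`` is (n_groups x n) boolean over samples already sorted by
    (time asc, events first at ties); returns S(horizon) per group (nan
    for empty groups).
    """
    relevant = member & (order_time <= horizon)[None, :] & (order_event == 1)[None, :]
    at_risk = np.cumsum(member[:, ::-1], axis=1)[:, ::-1].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_terms = np.where(
            relevant,
            np.log(np.maximum(at_risk - 1.0, 0.0)) - np.log(at_risk),
            0.0,
        )
    s = np.exp(log_terms.sum(axis=1))
    s[np.isneginf(log_terms).any(axis=1)] = 0.0
    empty = ~member.any(axis=1)
    s[empty] = np.nan
    return s


def td_roc(
    scores: np.ndarray,
    outcome: SurvivalOutcome,
    horizon: float,
) -> tuple[pd.DataFrame, float]:
    """Cumulative/dynamic ROC curve and AUC at a horizon.

    sensitivity(c) = P(score > c | event by horizon) and
    specificity(c) = P(score <= c | survival past horizon), both
    estimated through Kaplan–Meier survival within the score-defined
    groups so that censoring before the horizon is handled.  The AUC is
    the trapezoidal integral over all unique score cut points.
    """
    scores = np.asarray(scores, dtype=float)
    time, event = outcome.time, outcome.event
    if horizon <= 0 or horizon >= time.max():
        raise DataError("horizon must lie inside the observed time range")
    order = np.lexsort((1 - event, time))
    t_s, e_s, sc_s = time[order], event[order], scores[order]

    cuts = np.unique(scores)  # ascending; group "high" = score > cut
    member_high = sc_s[None, :] > cuts[:, None]
    member_low = ~member_high
    all_mask = np.ones((1, len(scores)), dtype=bool)

    s_marg = _km_at_horizon(all_mask, t_s, e_s, horizon)[0]
    f_marg = 1.0 - s_marg
    if f_marg <= 0:
        raise DataError("no cases by the horizon")
    if s_marg <= 0:
        raise DataError("no controls past the horizon")
    p_high = member_high.mean(axis=1)
    s_high = _km_at_horizon(member_high, t_s, e_s, horizon)
    s_low = _km_at_horizon(member_low, t_s, e_s, horizon)

    with np.errstate(invalid="ignore"):
        sens = (1.0 - s_high) * p_high / f_marg
        spec = s_low * (1.0 - p_high) / s_marg
    sens = np.clip(np.where(np.isnan(sens), 0.0, sens), 0.0, 1.0)
    spec = np.clip(np.where(np.isnan(spec), 0.0, spec), 0.0, 1.0)

    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    roc = pd.DataFrame(
        {"cut": np.concatenate([[-np.inf], cuts, [np.inf]]), "fpr": fpr, "tpr": tpr}
    )
    # round away 1e-15 noise so tied coordinates sort as ties, then walk the
    # staircase with TPR rising within each FPR level
    fpr_r, tpr_r = np.round(fpr, 10), np.round(tpr, 10)
    srt = np.lexsort((tpr_r, fpr_r))
    auc = float(np.trapezoid(tpr_r[srt], fpr_r[srt]))
    return roc, auc


def td_auc(scores, outcome: SurvivalOutcome, horizon: float) -> float:
    return td_roc(scores, outcome, horizon)[1]


@dataclass
class AUCComparison:
    """Basic-vs-optimized AUC contrast at one horizon with bootstrap inference."""

    horizon: float
    auc_basic: float
    auc_optimized: float
    delta: float
    relative_improvement: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    n_skipped: int

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "auc_basic": self.auc_basic,
            "auc_optimized": self.auc_optimized,
            "delta": self.delta,
            "relative_improvement": self.relative_improvement,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n_boot": self.n_boot,
            "n_skipped": self.n_skipped,
        }


def bootstrap_auc_compare(
    basic: RiskModel,
    optimized: RiskModel,
    design: pd.DataFrame,
    outcome: SurvivalOutcome,
    horizon: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> AUCComparison:
    """Percentile-bootstrap comparison of the two models' time-dependent AUC.

    Subjects are resampled with replacement; both models are REFIT on each
    replicate and their AUCs recomputed, so refitting optimism is part of
    the resampled distribution.  Replicates with degenerate fits or no
    cases/controls at the horizon are skipped and counted; more than 10%
    skipped aborts.  p is the two-sided sign-flip percentile p-value with
    a +1/(B+1) continuity correction.
    """
    if set(basic.terms) - set(optimized.terms):
        raise DataError("optimized model must contain all basic-model terms")
    basic_fit = basic.fitted(design, outcome)
    optim_fit = optimized.fitted(design, outcome)
    auc_b = td_auc(risk_score(basic_fit, design), outcome, horizon)
    auc_o = td_auc(risk_score(optim_fit, design), outcome, horizon)
    delta = auc_o - auc_b

    rng = np.random.default_rng(np.random.SeedSequence([seed, 32452843]))
    n = outcome.n
    deltas = []
    skipped = 0
    max_skipped = max(1, int(0.1 * n_boot))
    same_terms = list(basic.terms) == list(optimized.terms)
    while len(deltas) < n_boot:
        rows = rng.integers(0, n, size=n)
        d_b = design.iloc[rows].reset_index(drop=True)
        out_b = SurvivalOutcome(
            [f"b{i}" for i in range(n)], outcome.time[rows], outcome.event[rows]
        )
        try:
            fb = basic.fitted(d_b, out_b)
            ab = td_auc(risk_score(fb, d_b), out_b, horizon)
            if same_terms:
                ao = ab
            else:
                fo = optimized.fitted(d_b, out_b)
                ao = td_auc(risk_score(fo, d_b), out_b, horizon)
            if not (fb.fit.converged and (same_terms or fo.fit.converged)):
                raise CoxError("non-convergence")
        except (CoxError, DataError):
            skipped += 1
            if skipped > max_skipped:
                raise DataError(
                    f"more than 10% of bootstrap replicates degenerate "
                    f"({skipped} skipped)"
                )
            continue
        deltas.append(ao - ab)
    deltas = np.asarray(deltas)
    ci_low, ci_high = np.quantile(deltas, [0.025, 0.975])
    b = deltas.size
    p_low = (np.sum(deltas <= 0) + 1) / (b + 1)
    p_high = (np.sum(deltas >= 0) + 1) / (b + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return AUCComparison(
        horizon=horizon,
        auc_basic=auc_b,
        auc_optimized=auc_o,
        delta=delta,
        relative_improvement=delta / auc_b if auc_b else np.nan,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p=float(p),
        n_boot=n_boot,
        n_skipped=skipped,
    )


def dichotomize(values, rule="median", cutoff: float | None = None) -> tuple[np.ndarray, float]:
    """Split values into 'low'/'high' groups; ties at the cut go low.

    ``rule`` is ``"median"`` (cut at the sample median) or ``"fixed"``
    (cut at ``cutoff``).  Returns (labels, cut used).
    """
    values = np.asarray(values, dtype=float)
    if rule == "median":
        if np.unique(values).size < 2:
            raise DataError("cannot median-split constant values")
        cut = float(np.median(values))
    elif rule == "fixed":
        if cutoff is None:
            raise ValueError("fixed rule requires a cutoff")
        cut = float(cutoff)
    else:
        raise ValueError("rule must be 'median' or 'fixed'")
    labels = np.where(values <= cut, "low", "high")
    return labels, cut


@dataclass
class KMGroupResult:
    """Per-group product-limit estimates plus group contrast statistics."""

    curves: dict[str, pd.DataFrame]  # group -> (time, survival, at_risk, events)
    logrank_p: float | None
    hr_unadjusted: float | None
    hr_unadjusted_p: float | None
    hr_adjusted: float | None
    hr_adjusted_p: float | None


def _product_limit(time, event) -> pd.DataFrame:
    order = np.lexsort((1 - event, time))
    t_s, e_s = time[order], event[order]
    rows = []
    n_risk = len(t_s)
    surv = 1.0
    for t in np.unique(t_s):
        mask = t_s == t
        d = int(e_s[mask].sum())
        n_at = int((t_s >= t).sum())
        if d > 0:
            surv *= 1.0 - d / n_at
        rows.append((t, surv, n_at, d))
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk", "events"])


def km_curve(
    outcome: SurvivalOutcome,
    groups,
    covariates: pd.DataFrame | None = None,
) -> KMGroupResult:
    """Kaplan–Meier estimates per group with log-rank test and Cox group HR.

    The HR compares "high" vs "low" when the groups use those labels
    (otherwise the lexicographically later group vs earlier).  An adjusted
    HR is included when ``covariates`` is given.
    """
    groups = np.asarray(groups)
    levels = sorted(np.unique(groups).tolist())
    if len(levels) < 2:
        raise DataError("km_curve needs at least two groups")
    curves = {
        lvl: _product_limit(outcome.time[groups == lvl], outcome.event[groups == lvl])
        for lvl in levels
    }
    lr = multivariate_logrank_test(outcome.time, groups, outcome.event)
    # code the indicator so the reported HR is high-vs-low where applicable
    if set(levels) == {"low", "high"}:
        indicator = (groups == "high").astype(float)
    else:
        indicator = (groups == levels[-1]).astype(float)
    hr_u = hr_u_p = hr_a = hr_a_p = None
    try:
        fit_u = cox_fit(indicator[:, None], outcome.time, outcome.event, terms=["group"], warn=False)
        hr_u, hr_u_p = float(fit_u.hr[0]), float(fit_u.p[0])
    except CoxError:
        pass
    if covariates is not None and covariates.shape[1] > 0:
        try:
            X = np.column_stack([indicator, covariates.to_numpy(dtype=float)])
            fit_a = cox_fit(
                X, outcome.time, outcome.event,
                terms=["group"] + [str(c) for c in covariates.columns], warn=False,
            )
            hr_a, hr_a_p = float(fit_a.hr[0]), float(fit_a.p[0])
        except CoxError:
            pass
    return KMGroupResult(
        curves=curves,
        logrank_p=float(lr.p_value),
        hr_unadjusted=hr_u,
        hr_unadjusted_p=hr_u_p,
        hr_adjusted=hr_a,
        hr_adjusted_p=hr_a_p,
    )


def modifier_analysis(
    gene_a: str,
    gene_b: str,
    expr: pd.DataFrame,  # samples x genes, modelling scale
    covariates: pd.DataFrame,
    outcome: SurvivalOutcome,
    rule: str = "median",
    cutoff: float | None = None,
) -> dict:
    """Effect of gene_a within low/high strata of the modifier gene_b.

    Within each modifier stratum, gene_a's main-effect Cox model (gene +
    covariates) is refitted; additionally gene_a is median-split inside
    each stratum and the 2x2-group KM contrast computed.
    """
    for g in (gene_a, gene_b):
        if g not in expr.columns:
            raise DataError(f"gene {g!r} absent from expression")
    labels_b, cut_b = dichotomize(expr[gene_b].to_numpy(), rule, cutoff)
    strata = {}
    for level in ("low", "high"):
        rows = np.nonzero(labels_b == level)[0]
        if rows.size == 0:
            raise DataError(f"empty modifier stratum {level!r}")
        sub_out = SurvivalOutcome(
            [outcome.sample_ids[i] for i in rows],
            outcome.time[rows],
            outcome.event[rows],
        )
        sub_cov = covariates.iloc[rows]
        sub_cov = sub_cov.loc[:, sub_cov.nunique() > 1]
        x = expr[gene_a].to_numpy()[rows]
        entry: dict = {"n": int(rows.size), "n_events": sub_out.n_events, "cut": cut_b}
        try:
            X = np.column_stack([x, sub_cov.to_numpy(dtype=float)])
            fit = cox_fit(
                X, sub_out.time, sub_out.event,
                terms=[gene_a] + [str(c) for c in sub_cov.columns], warn=False,
            )
            entry.update(
                hr=float(fit.hr[0]), p=float(fit.p[0]), coef=float(fit.coef[0]),
                converged=fit.converged,
            )
        except CoxError as exc:
            entry.update(hr=np.nan, p=np.nan, coef=np.nan, converged=False, error=str(exc))
        try:
            labels_a, _ = dichotomize(x, "median")
            entry["km"] = km_curve(sub_out, labels_a, sub_cov)
        except DataError as exc:
            entry["km_error"] = str(exc)
        strata[level] = entry
    return strata
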