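"""Cox proportional-hazards fitting by Newton–Raphson on the partial likelihood.

The model is h(t) = h0(t) * exp(x'beta).  Tied event times are handled
with the Efron correction; when every event time is distinct the Efron,
Breslow and exact partial likelihoods coincide and a vectorized
cumulative-sum evaluation is used, which keeps large association scans
and bootstrap refits fast.

Wald standard errors come from the inverse observed information at the
maximum; 95% confidence intervals use the 1.96 normal quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import DataError

MAX_ITER = 50
TOL = 1e-9
#: |beta| beyond which the likelihood is treated as monotone (separation analogue)
DIVERGENCE_BOUND = 80.0


class CoxError(DataError):
    """Raised for structurally unfittable designs (no events, collinearity)."""


@dataclass
class CoxFit:
    """Result of one Cox model fit.

    ``coef`` are log-hazard ratios per unit of the design column;
    ``hr`` = exp(coef) with Wald 95% CI bounds.
    """

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    n_iter: int
    #: terms whose partial likelihood is monotone (coefficient drifting to
    #: +/- infinity, e.g. an indicator level with no events); their Wald SE
    #: is huge and their p-value uninformative, but the remaining terms are
    #: estimated normally
    monotone_terms: tuple[str, ...] = ()

    @property
    def hr(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.coef - 1.959963984540054 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.coef + 1.959963984540054 * self.se)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def term_index(self, term: str) -> int:
        return self.terms.index(term)

    def summary(self) -> "pd.DataFrame":  # noqa: F821 - optional convenience
        import pandas as pd

        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "hr": self.hr,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )


def _check_design(X: np.ndarray, terms: list[str]) -> None:
    if X.ndim != 2 or X.shape[1] != len(terms):
        raise CoxError("design matrix / term name mismatch")
    if not np.isfinite(X).all():
        raise CoxError("design matrix contains non-finite values")
    ptp = X.max(axis=0) - X.min(axis=0)
    constant = [terms[j] for j in np.nonzero(ptp == 0)[0]]
    if constant:
        raise CoxError(f"constant design columns: {constant}")
    if X.shape[1] > 1:
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < X.shape[1]:
            raise CoxError("collinear design columns (rank-deficient design)")


def _efron_quantities(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient, Hessian with Efron tie correction.

    Vectorized over tied-event groups: risk-set suffix sums plus
    per-group segment sums (np.add.reduceat), then one pass over the
    flattened (group, within-tie index) event rows.  Exact for any tie
    pattern.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    order = np.argsort(time, kind="mergesort")
    t_s, e_s = time[order], event[order]
    X_s, w_s, eta_s = X[order], w[order], eta[order]

    # suffix sums over the risk set {t >= t_group}
    wx = w_s[:, None] * X_s
    wxx = wx[:, :, None] * X_s[:, None, :]
    S_w = np.cumsum(w_s[::-1])[::-1]
    S_wx = np.cumsum(wx[::-1], axis=0)[::-1]
    S_wxx = np.cumsum(wxx[::-1], axis=0)[::-1]

    # tie groups among event times
    starts = np.nonzero(np.r_[True, t_s[1:] != t_s[:-1]])[0]
    dead = e_s == 1
    d_per = np.add.reduceat(dead.astype(np.int64), starts)
    has_event = d_per > 0
    g_starts = starts[has_event]
    d_g = d_per[has_event]

    # per-group dead-set sums
    wD = np.add.reduceat(np.where(dead, w_s, 0.0), starts)[has_event]
    ZD = np.add.reduceat(np.where(dead[:, None], wx, 0.0), starts, axis=0)[has_event]
    QD = np.add.reduceat(
        np.where(dead[:, None, None], wxx, 0.0), starts, axis=0
    )[has_event]
    S0, Z0, Q0 = S_w[g_starts], S_wx[g_starts], S_wxx[g_starts]

    # flatten to one row per event with its within-tie index l
    G = d_g.size
    rep = np.repeat(np.arange(G), d_g)
    offs = np.concatenate([[0], np.cumsum(d_g)[:-1]])
    l = np.arange(d_g.sum()) - offs[rep]
    frac = l / d_g[rep]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        phi = S0[rep] - frac * wD[rep]
        v = (Z0[rep] - frac[:, None] * ZD[rep]) / phi[:, None]
        M = (Q0[rep] - frac[:, None, None] * QD[rep]) / phi[:, None, None]
        ll = float(eta_s[dead].sum() - np.log(phi).sum())
    grad = X_s[dead].sum(axis=0) - v.sum(axis=0)
    hess = -(M.sum(axis=0) - v.T @ v)
    return ll, grad, hess


def _breslow_fast(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Vectorized likelihood/gradient/Hessian valid when event times are distinct.

    Subjects censored exactly at an event time remain in that event's risk
    set (the sort puts events first at equal times in descending order).
    """
    p = X.shape[1]
    eta = X @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    # descending time; at tied times events come last so the cumulative
    # risk-set sums at an event row include tied censored subjects
    order = np.lexsort((event, -time))
    e_s = event[order] == 1
    X_s, w_s, eta_s = X[order], w[order], eta[order]
    cw = np.cumsum(w_s)
    cwx = np.cumsum(w_s[:, None] * X_s, axis=0)
    wxx = w_s[:, None, None] * X_s[:, :, None] * X_s[:, None, :]
    cwxx = np.cumsum(wxx, axis=0)

    phi = cw[e_s]
    Z = cwx[e_s]
    Q = cwxx[e_s]
    v = Z / phi[:, None]
    ll = float(eta_s[e_s].sum() - np.log(phi).sum())
    grad = X_s[e_s].sum(axis=0) - v.sum(axis=0)
    hess = -(np.einsum("kij,k->ij", Q, 1.0 / phi) - v.T @ v)
    return ll, grad, hess


def cox_fit(
    X,
    time,
    event,
    terms: list[str] | None = None,
    ties: str = "efron",
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    warn: bool = True,
) -> CoxFit:
    """Fit a Cox model by Newton–Raphson with step-halving.

    Parameters
    ----------
    X
        (n x p) design matrix (DataFrame or array).
    time, event
        Observed times and 0/1 event indicators.
    ties
        Only ``"efron"`` is supported; when event times are distinct the
        equivalent vectorized evaluation is used automatically.

    Raises
    ------
    CoxError
        If there are no events, or the design has constant/collinear
        columns.  Non-convergence and monotone likelihood are reported via
        ``converged=False`` (with a warning), not an exception.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    if hasattr(X, "columns"):
        terms = terms or [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        terms = terms or [f"x{j}" for j in range(X.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    n_events = int(event.sum())
    if n_events < 1:
        raise CoxError("cannot fit a Cox model with no events")
    _check_design(X, terms)

    event_times = time[event == 1]
    tied = event_times.size != np.unique(event_times).size
    objective = _efron_quantities if tied else _breslow_fast

    beta = np.zeros(p)
    ll, grad, hess = objective(beta, X, time, event)
    converged = False
    diverged = False
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            diverged = True
            break
        # cap the step so a flat direction (e.g. a one-subject indicator)
        # walks out gradually and is caught by the plateau test instead of
        # overshooting to +/- infinity in one iteration
        biggest = np.max(np.abs(step))
        if biggest > 5.0:
            step *= 5.0 / biggest
        # step-halving until the likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            ll_new, grad_new, hess_new = objective(candidate, X, time, event)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        else:
            diverged = True
            break
        delta = np.max(np.abs(candidate - beta))
        dll = ll_new - ll
        beta, ll, grad, hess = candidate, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > DIVERGENCE_BOUND:
            diverged = True
            break
        if delta < tol:
            converged = True
            break
        # monotone likelihood: some coefficient drifts while the likelihood
        # has flattened out; accept the maximum, flag the drifting terms
        if abs(dll) <= 1e-9 * (abs(ll) + 1.0):
            converged = True
            monotone = np.max(np.abs(beta)) > 10.0
            break

    monotone_terms: tuple[str, ...] = ()
    if monotone:
        monotone_terms = tuple(
            terms[j] for j in np.nonzero(np.abs(beta) > 10.0)[0]
        )
    if monotone and warn:
        warnings.warn(
            f"monotone partial likelihood for terms {monotone_terms}; their "
            "coefficients are unbounded and their Wald tests uninformative",
            stacklevel=2,
        )
    if diverged and warn:
        warnings.warn(
            "Cox fit did not converge (monotone likelihood / diverging "
            "coefficients); estimates are unreliable",
            stacklevel=2,
        )
        converged = False

    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    return CoxFit(
        terms=list(terms),
        coef=beta,
        se=se,
        loglik=float(ll),
        n=n,
        n_events=n_events,
        converged=converged,
        n_iter=it,
        monotone_terms=monotone_terms,
    )
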