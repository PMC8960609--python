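"""Random survival forest with structurally forced covariate adjustment.

Each tree is grown on a bootstrap resample; at every internal node the
candidate variable set is the union of ALL clinical covariates and
``mtry`` randomly sampled genes (when ``covariates_forced``), so every
tree adjusts for every covariate by construction.  Splits maximize the
log-rank statistic over midpoints of sorted unique values; leaves store
the Nelson–Aalen cumulative-hazard "mortality" (the cumulative hazard
summed over the training grid of event times) of their in-bag members.

Out-of-bag (OOB) prediction error is 1 minus Harrell's concordance
index between ensemble OOB mortality and the observed outcomes, and
variable importance is permutation importance on the per-tree OOB error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .datatypes import DataError, SurvivalOutcome


@dataclass
class SurvivalForestConfig:
    """Hyperparameters of the covariate-forced survival forest."""

    n_trees: int = 1000
    mtry: int | str = "sqrt"
    min_node_size: int = 15
    covariates_forced: bool = True
    seed: int = 0

    def resolve_mtry(self, n_genes: int) -> int:
        if self.mtry == "sqrt":
            m = int(round(np.sqrt(n_genes)))
        else:
            m = int(self.mtry)
        if not 1 <= m <= n_genes:
            raise ValueError(f"mtry={m} outside [1, {n_genes}]")
        return m


@njit(cache=True)
def _best_split(Xc, f, ev, dd, nd):  # pragma: no cover - exercised via fit
    """Best log-rank split over all candidate columns of one node.

    Parameters are node-local: Xc (m x K) candidate values, f[i] = number
    of node event times <= t_i, ev event indicators, dd/nd per-event-time
    death and at-risk totals.  Returns (column, threshold, chi2); column
    is -1 when no admissible split exists.

    The statistic for the left group, U = sum_d (eL_d - dd_d * nL_d/nd_d)
    and its hypergeometric variance V, are maintained incrementally as
    samples cross the moving threshold, so each candidate column costs
    O(sum_i f_i) instead of O(cutpoints x event times).
    """
    m, K = Xc.shape
    D = dd.shape[0]
    best_chi = 0.0
    best_k = -1
    best_thr = 0.0
    # per-event-time constants shared by all candidate columns
    dn = np.empty(D)
    c2 = np.empty(D)
    for d in range(D):
        dn[d] = dd[d] / nd[d]
        if nd[d] > 1.0:
            c2[d] = dd[d] * (nd[d] - dd[d]) / ((nd[d] - 1.0) * nd[d] * nd[d])
        else:
            c2[d] = 0.0
    nL = np.zeros(D)
    for k in range(K):
        x = Xc[:, k]
        order = np.argsort(x, kind="mergesort")
        for d in range(D):
            nL[d] = 0.0
        U = 0.0
        V = 0.0
        for i in range(m - 1):
            idx = order[i]
            fi = f[idx]
            for d in range(fi):
                nl = nL[d] + 1.0
                nL[d] = nl
                V += c2[d] * (nd[d] - 2.0 * nl + 1.0)
                U -= dn[d]
            if ev[idx] == 1:
                U += 1.0
            nxt = x[order[i + 1]]
            if nxt > x[idx] and V > 1e-12:
                chi = U * U / V
                if chi > best_chi + 1e-12:
                    best_chi = chi
                    best_k = k
                    best_thr = 0.5 * (x[idx] + nxt)
    return best_k, best_thr, best_chi


def _risk_tables(time: np.ndarray, event: np.ndarray):
    """Unique event times with per-time death counts, at-risk counts, and f."""
    ut = np.unique(time[event == 1])
    f = np.searchsorted(ut, time, side="right").astype(np.int64)
    D = ut.size
    dd = np.zeros(D)
    nd = np.zeros(D)
    if D:
        np.add.at(dd, f[event == 1] - 1, 1.0)
        cnt = np.bincount(f, minlength=D + 1).astype(float)
        nd = cnt[::-1].cumsum()[::-1][1:]  # nd[d] = #{f_i > d}
    return ut, f, dd, nd


@njit(cache=True)
def _node_stats(t_sorted, e):  # pragma: no cover - exercised via fit
    """Risk tables of one node whose rows are already sorted by time.

    Returns (D, f, dd, nd, ut) as in :func:`_risk_tables`, in one linear
    pass (the hot path of tree growth).
    """
    m = t_sorted.shape[0]
    f = np.empty(m, dtype=np.int64)
    ut = np.empty(m)
    dd = np.zeros(m)
    D = 0
    for i in range(m):
        if e[i] == 1:
            if D == 0 or t_sorted[i] > ut[D - 1]:
                ut[D] = t_sorted[i]
                D += 1
            dd[D - 1] += 1.0
        f[i] = D  # number of distinct event times <= t_i so far
    nd = np.zeros(D)
    for i in range(m):
        if f[i] > 0:
            nd[f[i] - 1] += 1.0  # at risk up to its last covered event time
    # suffix-accumulate: at risk at d means f_i > d
    total = 0.0
    for d in range(D - 1, -1, -1):
        total += nd[d]
        nd[d] = total
    return D, f, dd[:D], nd, ut[:D]


def _nelson_aalen_mortality(time, event, grid) -> float:
    """Sum over the training grid of the Nelson–Aalen cumulative hazard."""
    ut, _, dd, nd = _risk_tables(time, event)
    if ut.size == 0:
        return 0.0
    hazard = dd / nd
    weight = grid.size - np.searchsorted(grid, ut, side="left")
    return float(np.sum(hazard * weight))


@njit(cache=True)
def _leaf_mortality(ut, dd, nd, grid):  # pragma: no cover - exercised via fit
    total = 0.0
    G = grid.shape[0]
    for d in range(ut.shape[0]):
        # number of grid times >= ut[d]
        lo, hi = 0, G
        while lo < hi:
            mid = (lo + hi) // 2
            if grid[mid] < ut[d]:
                lo = mid + 1
            else:
                hi = mid
        total += dd[d] / nd[d] * (G - lo)
    return total


@dataclass
class _Tree:
    feature: np.ndarray  # -1 for leaves
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray  # leaf mortality (nan for internal nodes)
    candidates: list[np.ndarray]  # candidate column set per internal node
    in_bag: np.ndarray
    oob: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = np.nonzero(self.feature[node] >= 0)[0]
        while active.size:
            nd = node[active]
            ft = self.feature[nd]
            go_left = X[active, ft] <= self.threshold[nd]
            node[active] = np.where(go_left, self.left[nd], self.right[nd])
            active = active[self.feature[node[active]] >= 0]
        return self.value[node]


@dataclass
class SurvivalForest:
    """Fitted ensemble; column order is [covariates..., genes...]."""

    trees: list[_Tree]
    covariate_names: list[str]
    gene_names: list[str]
    config: SurvivalForestConfig
    time: np.ndarray
    event: np.ndarray
    X: np.ndarray

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    def gene_column(self, gene: str) -> int:
        if gene not in self.gene_names:
            raise DataError(f"gene {gene!r} was not a forest feature")
        return self.n_covariates + self.gene_names.index(gene)

    def oob_mortality(self) -> np.ndarray:
        """Ensemble OOB mortality per sample (nan where never OOB)."""
        n = self.X.shape[0]
        total = np.zeros(n)
        count = np.zeros(n)
        for tree in self.trees:
            oob = tree.oob
            if oob.size == 0:
                continue
            total[oob] += tree.predict(self.X[oob])
            count[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def _grow_tree(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    grid: np.ndarray,
    cov_cols: np.ndarray,
    gene_cols: np.ndarray,
    mtry: int,
    min_node_size: int,
    forced: bool,
    rng: np.random.Generator,
) -> _Tree:
    n = X.shape[0]
    in_bag = rng.integers(0, n, size=n)
    oob = np.setdiff1d(np.arange(n), in_bag)
    # keep bag rows sorted by (time asc, events first at ties) so node
    # statistics can be computed in one linear pass
    in_bag = in_bag[np.lexsort((1 - event[in_bag], time[in_bag]))]
    Xb, tb, eb = X[in_bag], time[in_bag], event[in_bag]
    eb8 = eb.astype(np.uint8)

    feature, threshold, left, right, value, candidates = [], [], [], [], [], []
    all_cols = np.concatenate([cov_cols, gene_cols])

    def new_node():
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(np.nan)
        candidates.append(np.empty(0, dtype=np.int64))
        return len(feature) - 1

    root = new_node()
    stack = [(root, np.arange(n))]
    while stack:
        node_id, rows = stack.pop()
        t_nd, e_nd = tb[rows], eb8[rows]
        D, f, dd, nd, ut = _node_stats(t_nd, e_nd)
        if rows.size < 2 * min_node_size or D == 0:
            value[node_id] = _leaf_mortality(ut, dd, nd, grid)
            continue
        if forced:
            sampled = rng.choice(gene_cols, size=min(mtry, gene_cols.size), replace=False)
            cand = np.concatenate([cov_cols, sampled])
        else:
            cand = rng.choice(all_cols, size=min(mtry, all_cols.size), replace=False)
        k, thr, chi = _best_split(
            np.ascontiguousarray(Xb[np.ix_(rows, cand)]), f, e_nd, dd, nd
        )
        if k < 0 or chi <= 0.0:
            value[node_id] = _leaf_mortality(ut, dd, nd, grid)
            continue
        col = int(cand[k])
        go_left = Xb[rows, col] <= thr
        feature[node_id] = col
        threshold[node_id] = thr
        candidates[node_id] = np.sort(cand)
        left_id, right_id = new_node(), new_node()
        left[node_id], right[node_id] = left_id, right_id
        stack.append((left_id, rows[go_left]))
        stack.append((right_id, rows[~go_left]))

    return _Tree(
        feature=np.array(feature, dtype=np.int64),
        threshold=np.array(threshold),
        left=np.array(left, dtype=np.int64),
        right=np.array(right, dtype=np.int64),
        value=np.array(value),
        candidates=candidates,
        in_bag=in_bag,
        oob=oob,
    )


def fit_survival_forest(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: SurvivalOutcome,
    config: SurvivalForestConfig,
) -> SurvivalForest:
    """Grow the covariate-forced ensemble.

    ``features`` (samples x genes) and ``covariates`` (samples x encoded
    covariates) must be row-aligned with the outcome.
    """
    if features.shape[1] < 1:
        raise DataError("forest needs at least one gene feature")
    if features.shape[0] != outcome.n or covariates.shape[0] != outcome.n:
        raise DataError("features/covariates not aligned with outcome")
    if outcome.n < 20:
        raise DataError("forest needs at least 20 samples")
    if outcome.n_events < 1:
        raise DataError("forest needs at least one event")
    gene_names = [str(c) for c in features.columns]
    cov_names = [str(c) for c in covariates.columns]
    X = np.ascontiguousarray(
        np.column_stack([covariates.to_numpy(dtype=float), features.to_numpy(dtype=float)])
    )
    time, event = outcome.time, outcome.event
    grid = np.unique(time[event == 1])
    cov_cols = np.arange(len(cov_names), dtype=np.int64)
    gene_cols = np.arange(len(cov_names), X.shape[1], dtype=np.int64)
    mtry = config.resolve_mtry(len(gene_names))

    ss = np.random.SeedSequence([config.seed, 7919])
    trees = [
        _grow_tree(
            X, time, event, grid, cov_cols, gene_cols, mtry,
            config.min_node_size, config.covariates_forced,
            np.random.default_rng(child),
        )
        for child in ss.spawn(config.n_trees)
    ]
    return SurvivalForest(
        trees=trees,
        covariate_names=cov_names,
        gene_names=gene_names,
        config=config,
        time=time,
        event=event,
        X=X,
    )


def concordance_error(pred: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """1 - Harrell C between risk predictions and right-censored outcomes.

    Comparable pairs are (i, j) with t_i < t_j and subject i an event; a
    pair is concordant when the earlier-event subject has the higher
    predicted risk; prediction ties count 0.5.
    """
    pred = np.asarray(pred, dtype=float)
    lt = time[:, None] < time[None, :]
    comparable = lt & (event[:, None] == 1)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise DataError("no comparable pairs for concordance")
    gt = pred[:, None] > pred[None, :]
    ties = pred[:, None] == pred[None, :]
    concordant = (comparable & gt).sum() + 0.5 * (comparable & ties).sum()
    return float(1.0 - concordant / n_pairs)


def oob_error(forest: SurvivalForest, outcome: SurvivalOutcome | None = None) -> float:
    """Ensemble OOB error: 1 - Harrell C of OOB mortality predictions."""
    time = forest.time if outcome is None else outcome.time
    event = forest.event if outcome is None else outcome.event
    pred = forest.oob_mortality()
    seen = ~np.isnan(pred)
    if not seen.all():
        warnings.warn(
            f"{int((~seen).sum())} samples were never out-of-bag; excluded "
            "from the OOB error",
            stacklevel=2,
        )
    if not seen.any():
        raise DataError("no sample is out-of-bag in any tree")
    return concordance_error(pred[seen], time[seen], event[seen])


def variable_importance(forest: SurvivalForest) -> pd.Series:
    """Permutation importance of each gene on the per-tree OOB error.

    importance(g) = mean over trees of (OOB concordance error with g's
    OOB values permuted - baseline OOB error of that tree).  Genes unused
    by a tree contribute zero for that tree.  Covariates are adjustment
    terms and are not ranked.
    """
    n_trees = len(forest.trees)
    totals = np.zeros(len(forest.gene_names))
    ss = np.random.SeedSequence([forest.config.seed, 104729])
    gene_col_of = {
        forest.n_covariates + j: j for j in range(len(forest.gene_names))
    }
    for tree, child in zip(forest.trees, ss.spawn(n_trees)):
        oob = tree.oob
        if oob.size < 2:
            continue
        t_o, e_o = forest.time[oob], forest.event[oob]
        if (e_o == 1).sum() == 0 or np.unique(t_o).size < 2:
            continue
        X_o = forest.X[oob].copy()
        try:
            base = concordance_error(tree.predict(X_o), t_o, e_o)
        except DataError:
            continue
        used = np.unique(tree.feature[tree.feature >= 0])
        used_genes = [gene_col_of[c] for c in used if c in gene_col_of]
        rng = np.random.default_rng(child)
        for j in used_genes:
            col = forest.n_covariates + j
            saved = X_o[:, col].copy()
            X_o[:, col] = saved[rng.permutation(oob.size)]
            totals[j] += concordance_error(tree.predict(X_o), t_o, e_o) - base
            X_o[:, col] = saved
    return pd.Series(totals / n_trees, index=forest.gene_names)
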