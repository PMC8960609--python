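"""Survival forest: forced covariates, OOB error, permutation importance."""

import numpy as np
import pandas as pd
import pytest

from lncsurv.datatypes import DataError, SurvivalOutcome
from lncsurv.forest import (
    SurvivalForestConfig,
    concordance_error,
    fit_survival_forest,
    oob_error,
    variable_importance,
)


def brute_force_concordance_error(pred, time, event):
    num = den = 0.0
    n = len(pred)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if pred[i] > pred[j]:
                    num += 1
                elif pred[i] == pred[j]:
                    num += 0.5
    return 1.0 - num / den


def _frames(X, cov=None):
    feats = pd.DataFrame(X, columns=[f"g{j}" for j in range(X.shape[1])])
    if cov is None:
        cov = pd.DataFrame(index=feats.index)
    return feats, cov


class TestConcordanceError:
    def test_all_tied_predictions_give_half(self):
        time = np.arange(1.0, 11.0)
        assert concordance_error(np.zeros(10), time, np.ones(10, int)) == 0.5

    def test_perfect_risk_order_gives_zero(self):
        time = np.arange(1.0, 11.0)
        pred = -time  # earliest death = highest risk
        assert concordance_error(pred, time, np.ones(10, int)) == 0.0

    def test_four_subject_single_discordance_is_one_sixth(self):
        # comparable pairs: (1,2),(1,3),(1,4),(2,3),(2,4),(3,4); only (3,4)
        # is discordant under predictions (4,3,1,2)
        time = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([4.0, 3.0, 1.0, 2.0])
        assert concordance_error(pred, time, np.ones(4, int)) == pytest.approx(1 / 6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        time = rng.exponential(1.0, n)
        event = (rng.random(n) < 0.7).astype(int)
        pred = np.round(rng.normal(size=n), 1)  # rounded to create ties
        assert concordance_error(pred, time, event) == pytest.approx(
            brute_force_concordance_error(pred, time, event), abs=1e-12
        )

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(DataError):
            concordance_error(np.arange(3.0), np.ones(3), np.zeros(3, int))


@pytest.fixture(scope="module")
def fitted_forest(request):
    dataset, config = request.getfixturevalue("small_dataset")
    from lncsurv.design import encode_covariates
    from lncsurv.io import log_transform

    expr = log_transform(dataset.fpkm)
    feats = pd.DataFrame(expr.values().T, columns=expr.gene_ids)
    cov = encode_covariates(dataset.clinical)
    forest = fit_survival_forest(
        feats, cov, dataset.survival,
        SurvivalForestConfig(n_trees=40, seed=3),
    )
    return forest, dataset, config


class TestForestStructure:
    def test_every_internal_node_candidates_contain_all_covariates(self, fitted_forest):
        forest, _, _ = fitted_forest
        cov_cols = set(range(forest.n_covariates))
        checked = 0
        for tree in forest.trees:
            for node, feat in enumerate(tree.feature):
                if feat >= 0:
                    assert cov_cols <= set(tree.candidates[node].tolist())
                    checked += 1
        assert checked > 0

    def test_unforced_forest_sometimes_omits_covariates(self, fitted_forest):
        _, dataset, _ = fitted_forest
        from lncsurv.design import encode_covariates
        from lncsurv.io import log_transform

        expr = log_transform(dataset.fpkm)
        feats = pd.DataFrame(expr.values().T, columns=expr.gene_ids)
        cov = encode_covariates(dataset.clinical)
        forest = fit_survival_forest(
            feats, cov, dataset.survival,
            SurvivalForestConfig(n_trees=5, covariates_forced=False, seed=4),
        )
        cov_cols = set(range(forest.n_covariates))
        omissions = sum(
            not cov_cols <= set(tree.candidates[node].tolist())
            for tree in forest.trees
            for node, feat in enumerate(tree.feature)
            if feat >= 0
        )
        assert omissions > 0

    def test_single_tree_fit_is_deterministic(self, fitted_forest):
        _, dataset, _ = fitted_forest
        from lncsurv.design import encode_covariates
        from lncsurv.io import log_transform

        expr = log_transform(dataset.fpkm)
        feats = pd.DataFrame(expr.values().T, columns=expr.gene_ids)
        cov = encode_covariates(dataset.clinical)
        config = SurvivalForestConfig(n_trees=1, seed=9)
        t1 = fit_survival_forest(feats, cov, dataset.survival, config).trees[0]
        t2 = fit_survival_forest(feats, cov, dataset.survival, config).trees[0]
        np.testing.assert_array_equal(t1.feature, t2.feature)
        np.testing.assert_array_equal(t1.threshold, t2.threshold)
        np.testing.assert_array_equal(t1.value, t2.value)

    def test_root_splits_on_perfectly_separating_feature(self):
        # binary feature separating early from late deaths, no censoring:
        # the log-rank statistic is maximal at that split
        n = 40
        time = np.arange(1.0, n + 1)
        x = (time > n / 2).astype(float)
        rng = np.random.default_rng(1)
        noise = rng.normal(size=n)
        feats, cov = _frames(np.column_stack([noise, x]))
        outcome = SurvivalOutcome([f"s{i}" for i in range(n)], time, np.ones(n, int))
        forest = fit_survival_forest(
            feats, cov, outcome,
            SurvivalForestConfig(n_trees=8, mtry=2, min_node_size=5, seed=0),
        )
        for tree in forest.trees:
            assert tree.feature[0] == 1  # the separating column
            assert tree.threshold[0] == pytest.approx(0.5)


class TestOOBError:
    def test_matches_brute_force_on_small_sample(self):
        rng = np.random.default_rng(2)
        n = 50
        X = rng.normal(size=(n, 3))
        time = rng.exponential(np.exp(-X[:, 0]))
        outcome = SurvivalOutcome([f"s{i}" for i in range(n)], time, np.ones(n, int))
        feats, cov = _frames(X)
        forest = fit_survival_forest(
            feats, cov, outcome,
            SurvivalForestConfig(n_trees=30, min_node_size=5, seed=5),
        )
        err = oob_error(forest)
        pred = forest.oob_mortality()
        seen = ~np.isnan(pred)
        expected = brute_force_concordance_error(
            pred[seen], outcome.time[seen], outcome.event[seen]
        )
        assert err == pytest.approx(expected, abs=1e-12)

    def test_informative_forest_beats_chance(self, fitted_forest):
        forest, _, _ = fitted_forest
        assert oob_error(forest) < 0.45


class TestVariableImportance:
    def test_noise_gene_importance_centers_on_zero(self):
        rng = np.random.default_rng(6)
        n = 500
        X = rng.normal(size=(n, 4))
        time = rng.exponential(np.exp(-X[:, 0]))
        outcome = SurvivalOutcome([f"s{i}" for i in range(n)], time, np.ones(n, int))
        feats, cov = _frames(X)
        values = []
        for seed in range(10):
            forest = fit_survival_forest(
                feats, cov, outcome, SurvivalForestConfig(n_trees=20, seed=seed)
            )
            values.append(variable_importance(forest)["g3"])  # pure noise column
        values = np.asarray(values)
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean()) <= 2 * se + 1e-4

    def test_planted_gene_outranks_noise(self, fitted_forest):
        forest, dataset, config = fitted_forest
        importance = variable_importance(forest)
        planted = [config.gene_id(i) for i in config.informative_indices]
        noise_median = importance.drop(
            [config.gene_id(i) for i in range(10)], errors="ignore"
        ).median()
        for gene in planted:
            assert importance[gene] > noise_median

    def test_duplicated_gene_shares_importance(self):
        rng = np.random.default_rng(7)
        n = 300
        signal = rng.normal(size=n)
        noise = rng.normal(size=(n, 6))
        X = np.column_stack([signal, signal, noise])
        time = rng.exponential(np.exp(-1.2 * signal))
        outcome = SurvivalOutcome([f"s{i}" for i in range(n)], time, np.ones(n, int))
        feats, cov = _frames(X)
        forest = fit_survival_forest(
            feats, cov, outcome, SurvivalForestConfig(n_trees=60, min_node_size=10, seed=8)
        )
        importance = variable_importance(forest)
        noise_median = importance[[f"g{j}" for j in range(2, 8)]].median()
        assert importance["g0"] > noise_median
        assert importance["g1"] > noise_median


class TestPreconditions:
    def test_no_events_rejected(self):
        feats, cov = _frames(np.random.default_rng(0).normal(size=(25, 2)))
        outcome = SurvivalOutcome(
            [f"s{i}" for i in range(25)], np.arange(1.0, 26.0), np.zeros(25, int)
        )
        with pytest.raises(DataError, match="event"):
            fit_survival_forest(feats, cov, outcome, SurvivalForestConfig(n_trees=2))

    def test_too_few_samples_rejected(self):
        feats, cov = _frames(np.random.default_rng(0).normal(size=(10, 2)))
        outcome = SurvivalOutcome(
            [f"s{i}" for i in range(10)], np.arange(1.0, 11.0), np.ones(10, int)
        )
        with pytest.raises(DataError, match="20 samples"):
            fit_survival_forest(feats, cov, outcome, SurvivalForestConfig(n_trees=2))
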