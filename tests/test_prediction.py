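"""Time-dependent ROC/AUC, bootstrap model comparison, KM analyses."""

import numpy as np
import pandas as pd
import pytest

from lncsurv.cox import cox_fit
from lncsurv.datatypes import DataError, SurvivalOutcome
from lncsurv.prediction import (
    RiskModel,
    bootstrap_auc_compare,
    dichotomize,
    km_curve,
    modifier_analysis,
    risk_score,
    td_auc,
    td_roc,
    _product_limit,
)


def brute_force_td_auc(scores, time, horizon):
    """All case-control score pairs on uncensored data, ties 0.5."""
    cases = time <= horizon
    controls = ~cases
    total = correct = 0.0
    for a in scores[cases]:
        for b in scores[controls]:
            total += 1
            if a > b:
                correct += 1
            elif a == b:
                correct += 0.5
    return correct / total


def _outcome(time, event=None):
    time = np.asarray(time, dtype=float)
    if event is None:
        event = np.ones(time.size, int)
    return SurvivalOutcome([f"s{i}" for i in range(time.size)], time, event)


class TestRiskScore:
    def test_zero_coefficients_give_zero_scores(self):
        design = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        model = RiskModel("basic", ["a", "b"])
        model.fit = cox_fit(
            np.array([[0.0, 1], [1, 0], [1, 1], [0, 0]]),
            np.arange(1.0, 5.0),
            np.ones(4, int),
            terms=["a", "b"],
        )
        model.fit.coef = np.zeros(2)
        np.testing.assert_array_equal(risk_score(model, design), np.zeros(2))

    def test_scores_match_hand_dot_products(self, small_dataset):
        dataset, _ = small_dataset
        design = pd.DataFrame({"a": [1.0, 0.0, 2.0], "b": [0.5, 1.0, -1.0]})
        model = RiskModel("basic", ["a", "b"])
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        model = model.fitted(
            pd.DataFrame(X, columns=["a", "b"]),
            _outcome(rng.exponential(1, 30)),
        )
        scores = risk_score(model, design)
        expected = design.to_numpy() @ model.fit.coef
        np.testing.assert_allclose(scores, expected, atol=1e-12)
        shifted = risk_score(model, design.assign(a=design["a"] + 10.0))
        np.testing.assert_allclose(
            shifted - scores, 10.0 * model.fit.coef[0], atol=1e-12
        )


class TestTdAUC:
    def test_null_scores_concentrate_on_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        t = rng.exponential(1, n)
        c = rng.exponential(2, n)
        outcome = _outcome(np.minimum(t, c), (t <= c).astype(int))
        auc = td_auc(rng.normal(size=n), outcome, 0.7)
        assert 0.46 < auc < 0.54

    def test_perfectly_ordering_scores_give_one(self):
        time = np.arange(1.0, 21.0)
        outcome = _outcome(time)
        assert td_auc(-time, outcome, 10.5) == pytest.approx(1.0)

    def test_five_subject_toy_by_cutpoint_enumeration(self, toy_outcome):
        # horizon 2.5: cases {t=1,2}, controls {t=3,4,5}; scores 5,4,3,2,1
        # rank cases strictly above controls at every cut -> AUC 1
        roc, auc = td_roc(np.array([5.0, 4, 3, 2, 1]), toy_outcome, 2.5)
        assert auc == pytest.approx(1.0)
        interior = roc.iloc[1:-1]
        assert interior["tpr"].iloc[-1] == pytest.approx(0.0)  # cut above all scores
        # at the cut separating cases from controls: sens 1, spec 1
        sep = roc[np.isclose(roc["cut"], 3.0)]
        assert sep["tpr"].iloc[0] == pytest.approx(1.0)
        assert sep["fpr"].iloc[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_pair_enumeration_on_uncensored_data(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        time = rng.exponential(1.0, n)
        scores = np.round(-time + rng.normal(0, 0.7, n), 1)
        outcome = _outcome(time)
        horizon = float(np.median(time) * 1.1)
        assert td_auc(scores, outcome, horizon) == pytest.approx(
            brute_force_td_auc(scores, time, horizon), abs=1e-9
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        n = 300
        t = rng.exponential(1, n)
        c = rng.exponential(1.5, n)
        outcome = _outcome(np.minimum(t, c), (t <= c).astype(int))
        scores = rng.normal(size=n)
        a1 = td_auc(scores, outcome, 0.8)
        a2 = td_auc(np.exp(3.0 * scores) + 5.0, outcome, 0.8)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_horizon_outside_range_rejected(self, toy_outcome):
        with pytest.raises(DataError, match="horizon"):
            td_auc(np.arange(5.0), toy_outcome, 10.0)

    def test_no_cases_rejected(self, toy_outcome):
        with pytest.raises(DataError, match="cases"):
            td_auc(np.arange(5.0), toy_outcome, 0.5)


class TestBootstrapCompare:
    @pytest.fixture(scope="class")
    def design_outcome(self):
        rng = np.random.default_rng(5)
        n = 250
        design = pd.DataFrame(
            {"cov": rng.normal(size=n), "gene": rng.normal(size=n)}
        )
        t = rng.exponential(np.exp(-0.9 * design["gene"] - 0.2 * design["cov"]))
        c = rng.exponential(1.5, n)
        return design, _outcome(np.minimum(t, c), np.asarray(t <= c, int))

    def test_identical_models_give_zero_delta_and_p_one(self, design_outcome):
        design, outcome = design_outcome
        cmp = bootstrap_auc_compare(
            RiskModel("basic", ["cov"]), RiskModel("optimized", ["cov"]),
            design, outcome, 0.7, n_boot=50, seed=0,
        )
        assert cmp.delta == 0.0
        assert cmp.ci_low == cmp.ci_high == 0.0
        assert cmp.p > 0.9

    def test_added_signal_gene_detected(self, design_outcome):
        design, outcome = design_outcome
        cmp = bootstrap_auc_compare(
            RiskModel("basic", ["cov"]), RiskModel("optimized", ["cov", "gene"]),
            design, outcome, 0.7, n_boot=100, seed=0,
        )
        assert cmp.auc_optimized > cmp.auc_basic
        assert cmp.ci_low > 0.0
        assert cmp.p < 0.05
        assert cmp.ci_low <= cmp.delta <= cmp.ci_high
        assert cmp.relative_improvement == pytest.approx(
            (cmp.auc_optimized - cmp.auc_basic) / cmp.auc_basic
        )

    def test_same_seed_reproduces_ci_and_p(self, design_outcome):
        design, outcome = design_outcome
        kwargs = dict(
            basic=RiskModel("basic", ["cov"]),
            optimized=RiskModel("optimized", ["cov", "gene"]),
            design=design, outcome=outcome, horizon=0.7, n_boot=40, seed=11,
        )
        a = bootstrap_auc_compare(**kwargs)
        b = bootstrap_auc_compare(**kwargs)
        assert (a.ci_low, a.ci_high, a.p) == (b.ci_low, b.ci_high, b.p)

    def test_basic_terms_must_nest_in_optimized(self, design_outcome):
        design, outcome = design_outcome
        with pytest.raises(DataError, match="contain"):
            bootstrap_auc_compare(
                RiskModel("basic", ["cov", "gene"]), RiskModel("optimized", ["gene"]),
                design, outcome, 0.7, n_boot=10, seed=0,
            )


class TestKaplanMeier:
    def test_five_subject_product_limit_by_hand(self):
        # times 1, 2+, 3, 4+, 5 -> S = 0.8, 0.8, 0.533, 0.533, 0
        curve = _product_limit(
            np.array([1.0, 2, 3, 4, 5]), np.array([1, 0, 1, 0, 1])
        )
        np.testing.assert_allclose(
            curve["survival"], [0.8, 0.8, 8 / 15, 8 / 15, 0.0], atol=1e-12
        )

    def test_no_events_survival_stays_one(self):
        curve = _product_limit(np.arange(1.0, 6.0), np.zeros(5, int))
        np.testing.assert_array_equal(curve["survival"], np.ones(5))

    def test_group_contrast_on_planted_gene(self, small_dataset):
        dataset, config = small_dataset
        from lncsurv.io import log_transform

        expr = log_transform(dataset.fpkm)
        gene = config.gene_id(config.informative_indices[0])  # harmful, log HR 0.6
        labels, _ = dichotomize(expr.data.loc[gene].to_numpy(), "median")
        km = km_curve(dataset.survival, labels)
        assert km.hr_unadjusted > 1.0
        assert km.logrank_p < 0.01

    def test_exchangeable_groups_near_null(self):
        rng = np.random.default_rng(6)
        hrs, ps = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 200
            time = rng.exponential(1, n)
            groups = np.where(rng.random(n) < 0.5, "low", "high")
            km = km_curve(_outcome(time), groups)
            hrs.append(km.hr_unadjusted)
            ps.append(km.logrank_p)
        assert np.median(np.abs(np.log(hrs))) < 0.25
        assert (np.asarray(ps) > 0.05).sum() >= 6

    def test_single_group_rejected(self, toy_outcome):
        with pytest.raises(DataError, match="two groups"):
            km_curve(toy_outcome, np.array(["a"] * 5))


class TestDichotomize:
    def test_median_rule_with_recorded_cut(self):
        labels, cut = dichotomize(np.array([1.0, 2, 3, 4]), "median")
        assert cut == 2.5
        np.testing.assert_array_equal(labels, ["low", "low", "high", "high"])

    def test_fixed_cutoff_applied_verbatim_ties_go_low(self):
        labels, cut = dichotomize(np.array([3.25, 3.26, 3.27]), "fixed", cutoff=3.26)
        assert cut == 3.26
        np.testing.assert_array_equal(labels, ["low", "low", "high"])

    def test_constant_values_rejected_under_median(self):
        with pytest.raises(DataError, match="constant"):
            dichotomize(np.ones(4), "median")


class TestModifierAnalysis:
    @pytest.fixture(scope="class")
    def planted_modifier(self):
        """Qualitative interaction: gene a protective in low-b, harmful in high-b."""
        rng = np.random.default_rng(8)
        n = 600
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        beta_a = np.where(b <= 0, -0.8, 0.8)
        t = rng.exponential(np.exp(-beta_a * a))
        c = rng.exponential(1.5, n)
        expr = pd.DataFrame({"ga": a, "gb": b})
        cov = pd.DataFrame({"age": rng.normal(60, 8, n)})
        return expr, cov, _outcome(np.minimum(t, c), (t <= c).astype(int))

    def test_recovers_opposite_stratum_effects(self, planted_modifier):
        expr, cov, outcome = planted_modifier
        strata = modifier_analysis("ga", "gb", expr, cov, outcome)
        assert strata["low"]["hr"] < 1.0 < strata["high"]["hr"]
        assert strata["low"]["p"] < 0.05 and strata["high"]["p"] < 0.05
        assert "km" in strata["low"]

    def test_stratum_fit_reproduces_direct_cox_fit(self, planted_modifier):
        expr, cov, outcome = planted_modifier
        strata = modifier_analysis("ga", "gb", expr, cov, outcome)
        labels, _ = dichotomize(expr["gb"].to_numpy(), "median")
        rows = np.nonzero(labels == "low")[0]
        X = np.column_stack(
            [expr["ga"].to_numpy()[rows], cov["age"].to_numpy()[rows]]
        )
        direct = cox_fit(
            X, outcome.time[rows], outcome.event[rows], terms=["ga", "age"]
        )
        assert strata["low"]["coef"] == pytest.approx(direct.coef[0], abs=1e-12)
        assert strata["low"]["p"] == pytest.approx(direct.p[0], abs=1e-12)

    def test_no_interaction_gives_agreeing_strata(self):
        rng = np.random.default_rng(9)
        n = 800
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * a))
        expr = pd.DataFrame({"ga": a, "gb": b})
        cov = pd.DataFrame({"age": rng.normal(60, 8, n)})
        strata = modifier_analysis("ga", "gb", expr, cov, _outcome(t))
        assert abs(
            np.log(strata["low"]["hr"]) - np.log(strata["high"]["hr"])
        ) < 0.35
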