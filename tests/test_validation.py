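"""Surrogate mapping, trans-platform verdicts, histology stratification."""

import numpy as np
import pandas as pd
import pytest

from lncsurv.association import main_effect_scan
from lncsurv.datatypes import DataError, Dataset, ExpressionMatrix, SurvivalOutcome
from lncsurv.design import encode_covariates
from lncsurv.io import log_transform
from lncsurv.simulate import SimulationConfig, simulate_two_phase
from lncsurv.validation import find_surrogates, stratified_analysis, validate_terms


@pytest.fixture(scope="module")
def two_phase():
    config = SimulationConfig(
        n_subjects=400,
        n_genes=30,
        n_informative_main=2,
        main_log_hr=0.7,
        interaction_log_hr=0.6,
        platform_overlap_fraction=0.7,
        seed=31,
    )
    return simulate_two_phase(config, n_validation=450)


class TestFindSurrogates:
    def test_gene_on_both_platforms_maps_to_itself(self, two_phase):
        discovery, validation, truth = two_phase
        shared = [g for g in discovery.fpkm.gene_ids if g in validation.fpkm.gene_ids]
        surrogate_map = find_surrogates(
            shared[:2], discovery.fpkm, validation.fpkm.gene_ids
        )
        for g in shared[:2]:
            entry = surrogate_map[g]
            assert entry.is_identity and entry.surrogate == g and entry.r == 1.0

    def test_missing_truth_gene_maps_to_block_partner(self, two_phase):
        discovery, validation, truth = two_phase
        val_genes = set(validation.fpkm.gene_ids)
        surrogate_map = find_surrogates(
            truth.informative_gene_ids, discovery.fpkm, validation.fpkm.gene_ids
        )
        for g in truth.informative_gene_ids:
            entry = surrogate_map[g]
            assert not entry.is_identity
            assert entry.surrogate in set(truth.block_partners[g]) & val_genes
            assert entry.q <= 0.05
            assert abs(entry.r) > 0.8

    def test_no_eligible_surrogate_is_unresolvable_not_arbitrary(self):
        # platform genes exactly orthogonal to the target: r = 0, q = 1
        values = np.array(
            [
                [-1.0, 1.0, -1.0, 1.0],
                [1.0, 1.0, -1.0, -1.0],
                [-1.0, 1.0, 1.0, -1.0],
            ]
        )
        expr = ExpressionMatrix(
            pd.DataFrame(
                2.0 ** values,
                index=["g0", "g1", "g2"],
                columns=[f"s{j}" for j in range(4)],
            ),
            "fpkm",
        )
        surrogate_map = find_surrogates(["g0"], expr, ["g1", "g2"])
        assert surrogate_map["g0"].surrogate is None

    def test_determinism(self, two_phase):
        discovery, validation, truth = two_phase
        targets = truth.informative_gene_ids
        a = find_surrogates(targets, discovery.fpkm, validation.fpkm.gene_ids)
        b = find_surrogates(targets, discovery.fpkm, validation.fpkm.gene_ids)
        assert a.to_frame().equals(b.to_frame())

    def test_zero_variance_target_rejected(self):
        values = np.ones((3, 10))
        values[1:] = np.random.default_rng(1).exponential(size=(2, 10))
        expr = ExpressionMatrix(
            pd.DataFrame(values, index=["g0", "g1", "g2"], columns=[f"s{j}" for j in range(10)]),
            "fpkm",
        )
        with pytest.raises(DataError, match="variance"):
            find_surrogates(["g0"], expr, ["g1", "g2"])


class TestValidateTerms:
    def test_planted_main_effects_pass_both_criteria(self, two_phase):
        discovery, validation, truth = two_phase
        expr = log_transform(discovery.fpkm)
        cov = encode_covariates(discovery.clinical)
        results = main_effect_scan(
            expr, truth.informative_gene_ids, cov, discovery.survival
        )
        surrogate_map = find_surrogates(
            truth.informative_gene_ids, discovery.fpkm, validation.fpkm.gene_ids
        )
        verdicts = validate_terms(results, surrogate_map, validation)
        assert all(v.passed for v in verdicts)
        for v in verdicts:
            assert v.validation.p <= 0.05
            assert v.validation.direction == v.discovery.direction

    def test_identity_self_validation_reproduces_discovery(self, two_phase):
        """Using the discovery cohort as a mock validation set with identity
        surrogates must reproduce the discovery fits exactly."""
        discovery, _, truth = two_phase
        expr = log_transform(discovery.fpkm)
        cov = encode_covariates(discovery.clinical)
        targets = truth.informative_gene_ids
        results = main_effect_scan(expr, targets, cov, discovery.survival)
        surrogate_map = find_surrogates(targets, discovery.fpkm, discovery.fpkm.gene_ids)
        verdicts = validate_terms(results, surrogate_map, discovery)
        for v, r in zip(verdicts, results):
            assert v.validation.coef == pytest.approx(r.coef, abs=1e-10)
            assert v.validation.p == pytest.approx(r.p, abs=1e-10)
            assert v.passed  # discovery hits trivially self-validate

    def test_failure_reasons_name_the_violated_criterion(self, two_phase):
        discovery, validation, truth = two_phase
        expr = log_transform(discovery.fpkm)
        cov = encode_covariates(discovery.clinical)
        targets = truth.informative_gene_ids[:1]
        results = main_effect_scan(expr, targets, cov, discovery.survival)
        surrogate_map = find_surrogates(targets, discovery.fpkm, validation.fpkm.gene_ids)
        # force criterion 1 to fail: inflate validation p by flipping events off
        verdict_p = validate_terms(results, surrogate_map, validation, p_threshold=1e-12)
        assert not verdict_p[0].passed
        assert any("p >" in r for r in verdict_p[0].reasons)
        # force criterion 2 to fail: negate the discovery direction
        flipped = results[0]
        flipped.coef = -flipped.coef
        verdict_d = validate_terms([flipped], surrogate_map, validation)
        assert not verdict_d[0].passed
        assert "direction flip" in verdict_d[0].reasons

    def test_unresolvable_surrogate_fails_with_reason(self, two_phase):
        discovery, validation, truth = two_phase
        expr = log_transform(discovery.fpkm)
        cov = encode_covariates(discovery.clinical)
        targets = truth.informative_gene_ids[:1]
        results = main_effect_scan(expr, targets, cov, discovery.survival)
        from lncsurv.validation import SurrogateEntry, SurrogateMap

        empty = SurrogateMap(
            {targets[0]: SurrogateEntry(targets[0], None, np.nan, np.nan, np.nan, False)}
        )
        verdicts = validate_terms(results, empty, validation)
        assert not verdicts[0].passed
        assert any("no eligible surrogate" in r for r in verdicts[0].reasons)


class TestStratifiedAnalysis:
    def test_homogeneous_effect_agrees_across_strata(self, two_phase):
        discovery, _, truth = two_phase
        expr = log_transform(discovery.fpkm)
        cov = encode_covariates(discovery.clinical)
        results = main_effect_scan(
            expr, truth.informative_gene_ids[:1], cov, discovery.survival
        )
        table = stratified_analysis(results, discovery)
        assert set(table["stratum"]) == {"LUAD", "LUSC"}
        log_hrs = np.log(table["hr"].to_numpy())
        assert np.sign(log_hrs[0]) == np.sign(log_hrs[1])
        assert abs(log_hrs[0] - log_hrs[1]) < 0.6  # Monte-Carlo tolerance

    def test_small_stratum_flagged_unstable(self):
        rng = np.random.default_rng(3)
        n = 60
        gene = rng.normal(size=n)
        clinical = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "age": rng.normal(65, 9, n),
                "gender": rng.choice(["Male", "Female"], n),
                "race": ["White"] * n,
                "smoke_status": rng.choice(["Former", "Current"], n),
                "pack_years": rng.normal(40, 10, n),
                "clinical_stage": rng.choice(["I", "II"], n),
                "histology": ["LUAD"] * 52 + ["LUSC"] * 8,
            }
        )
        fpkm = ExpressionMatrix(
            pd.DataFrame(2.0 ** gene[None, :], index=["g0"], columns=clinical["sample_id"]),
            "fpkm",
        )
        time = rng.exponential(1, n)
        event = (rng.random(n) < 0.6).astype(int)
        outcome = SurvivalOutcome(clinical["sample_id"].tolist(), time, event)
        dataset = Dataset(fpkm=fpkm, clinical=clinical, survival=outcome)
        expr = log_transform(fpkm)
        cov = encode_covariates(clinical)
        results = main_effect_scan(expr, ["g0"], cov, outcome)
        table = stratified_analysis(results, dataset)
        lusc = table[table["stratum"] == "LUSC"].iloc[0]
        assert bool(lusc["unstable"])
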