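"""End-to-end orchestration of the two-phase workflow.

Discovery phase: QC -> (FPKM branch, TMM branch) -> forest screening on
the FPKM branch -> main-effect and interaction scans on both branches ->
sensitivity intersection.  Validation phase: surrogate mapping ->
validation refits -> verdicts -> histology-stratified analysis ->
basic-vs-optimized time-dependent AUC comparison at the 3- and 5-year
horizons.  Every run can write a manifest (config, seed, input hashes,
versions) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import (
    AssociationResult,
    interaction_scan,
    main_effect_scan,
    results_to_frame,
    sensitivity_intersection,
)
from .datatypes import DataError, Dataset, ExpressionMatrix
from .design import encode_covariates
from .forest import SurvivalForestConfig
from .io import log_transform, qc_filter_genes, qc_filter_samples
from .normalization import apply_factors, tmm_factors
from .prediction import AUCComparison, RiskModel, bootstrap_auc_compare
from .screening import OOBCurve, VISRanking, rank_genes, swsfs_select
from .validation import (
    SurrogateMap,
    ValidationVerdict,
    find_surrogates,
    stratified_analysis,
    validate_terms,
)


@dataclass
class PipelineConfig:
    """Settings of the full two-phase run."""

    qc_max_missing: float = 0.10
    transform: str = "log2p1"  # or "none"
    forest_n_trees: int = 300
    swsfs_n_trees: int = 100
    mtry: int | str = "sqrt"
    min_node_size: int = 15
    covariates_forced: bool = True
    swsfs_window: int = 5
    k_max: int = 25
    q_discovery: float = 0.05
    p_validation: float = 0.05
    require_direction: bool = True
    n_boot: int = 1000
    horizons: tuple[float, ...] = (3.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("qc_max_missing", "q_discovery", "p_validation"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.transform not in ("log2p1", "none"):
            raise ValueError("transform must be 'log2p1' or 'none'")
        if self.swsfs_window < 1 or self.swsfs_window % 2 == 0:
            raise ValueError("swsfs_window must be an odd positive integer")

    def _seed_for(self, *stream: int) -> int:
        return int(
            np.random.SeedSequence([self.seed, *stream]).generate_state(1)[0] % (2**31)
        )

    def ranking_forest_config(self) -> SurvivalForestConfig:
        return SurvivalForestConfig(
            n_trees=self.forest_n_trees,
            mtry=self.mtry,
            min_node_size=self.min_node_size,
            covariates_forced=self.covariates_forced,
            seed=self._seed_for(1),
        )

    def swsfs_forest_config(self) -> SurvivalForestConfig:
        return SurvivalForestConfig(
            n_trees=self.swsfs_n_trees,
            mtry=self.mtry,
            min_node_size=self.min_node_size,
            covariates_forced=self.covariates_forced,
            seed=self._seed_for(2),
        )


def _modelling_matrix(expr: ExpressionMatrix, config: PipelineConfig) -> ExpressionMatrix:
    if config.transform == "log2p1" and expr.unit != "log2":
        return log_transform(expr)
    return expr


def _features_frame(expr: ExpressionMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        expr.values().T, columns=expr.gene_ids, index=expr.sample_ids
    )


@dataclass
class DiscoveryReport:
    dataset: Dataset
    gene_qc: pd.DataFrame
    stage_counts: dict[str, int]
    ranking: VISRanking
    oob_curve: OOBCurve
    candidates: list[str]
    main_fpkm: list[AssociationResult]
    main_tmm: list[AssociationResult]
    interaction_fpkm: list[AssociationResult]
    interaction_tmm: list[AssociationResult]
    retained_main: list[AssociationResult]
    retained_interaction: list[AssociationResult]
    intersection_log: pd.DataFrame

    @property
    def retained(self) -> list[AssociationResult]:
        return self.retained_main + self.retained_interaction

    def significant_genes(self) -> list[str]:
        genes: list[str] = []
        for r in self.retained:
            for g in r.genes:
                if g not in genes:
                    genes.append(g)
        return genes


def run_discovery(dataset: Dataset, config: PipelineConfig) -> DiscoveryReport:
    """Execute the discovery phase on one cohort.

    The screening forest runs on the FPKM branch only; the TMM branch is
    a sensitivity re-test of the screened candidates.  Raises
    :class:`DataError` with stage-named diagnostics on degenerate stages.
    """
    counts_in = {"samples_in": dataset.fpkm.n_samples, "genes_in": dataset.fpkm.n_genes}
    fpkm_filtered, gene_report = qc_filter_genes(dataset.fpkm, config.qc_max_missing)
    aligned = qc_filter_samples(
        fpkm_filtered, dataset.clinical, dataset.survival, dataset.counts
    )
    if aligned.counts is not None:
        counts_qc = aligned.counts.subset_genes(
            [g for g in fpkm_filtered.gene_ids if g in aligned.counts.data.index]
        )
    else:
        counts_qc = None
    stage_counts = {
        **counts_in,
        "genes_removed_qc": len(gene_report.removed),
        "samples_retained": aligned.fpkm.n_samples,
        "genes_retained": aligned.fpkm.n_genes,
    }

    fpkm_branch = _modelling_matrix(aligned.fpkm, config)
    covariates = encode_covariates(aligned.clinical)
    outcome = aligned.survival

    ranking, _ = rank_genes(
        _features_frame(fpkm_branch), covariates, outcome, config.ranking_forest_config()
    )
    candidates, curve = swsfs_select(
        _features_frame(fpkm_branch),
        covariates,
        outcome,
        ranking,
        config.swsfs_forest_config(),
        window=config.swsfs_window,
        k_max=config.k_max,
    )
    stage_counts["candidates"] = len(candidates)

    main_fpkm = main_effect_scan(fpkm_branch, candidates, covariates, outcome)
    if len(candidates) >= 2:
        inter_fpkm = interaction_scan(fpkm_branch, candidates, covariates, outcome)
    else:
        inter_fpkm = []

    if counts_qc is None:
        raise DataError("TMM branch requires a counts matrix")
    tmm_branch = apply_factors(counts_qc, tmm_factors(counts_qc))
    tmm_branch = _modelling_matrix(tmm_branch, config)
    tmm_candidates = [g for g in candidates if g in tmm_branch.data.index]
    main_tmm = main_effect_scan(tmm_branch, tmm_candidates, covariates, outcome)
    if len(tmm_candidates) >= 2:
        inter_tmm = interaction_scan(tmm_branch, tmm_candidates, covariates, outcome)
    else:
        inter_tmm = []

    retained_main, log_main = sensitivity_intersection(
        main_fpkm, main_tmm, config.q_discovery, config.require_direction
    )
    retained_inter, log_inter = sensitivity_intersection(
        inter_fpkm, inter_tmm, config.q_discovery, config.require_direction
    )
    stage_counts["retained_main"] = len(retained_main)
    stage_counts["retained_interaction"] = len(retained_inter)

    return DiscoveryReport(
        dataset=aligned,
        gene_qc=gene_report.to_frame(),
        stage_counts=stage_counts,
        ranking=ranking,
        oob_curve=curve,
        candidates=candidates,
        main_fpkm=main_fpkm,
        main_tmm=main_tmm,
        interaction_fpkm=inter_fpkm,
        interaction_tmm=inter_tmm,
        retained_main=retained_main,
        retained_interaction=retained_inter,
        intersection_log=pd.concat(
            [f for f in (log_main, log_inter) if not f.empty] or [log_main],
            ignore_index=True,
        ),
    )


@dataclass
class ValidationReport:
    surrogate_map: SurrogateMap
    verdicts: list[ValidationVerdict]
    stratified_discovery: pd.DataFrame | None
    stratified_validation: pd.DataFrame | None
    auc_comparisons: list[AUCComparison]
    manifest: dict = field(default_factory=dict)

    @property
    def passed(self) -> list[ValidationVerdict]:
        return [v for v in self.verdicts if v.passed]


def _auc_design(
    dataset: Dataset, genes: list[str], pairs: list[tuple[str, str]], config: PipelineConfig
) -> tuple[pd.DataFrame, list[str], list[str]]:
    expr = _modelling_matrix(dataset.fpkm, config)
    covariates = encode_covariates(dataset.clinical)
    design = covariates.reset_index(drop=True).copy()
    basic_terms = [str(c) for c in covariates.columns]
    extra: list[str] = []
    frame = _features_frame(expr).reset_index(drop=True)
    for g in genes:
        design[g] = frame[g]
        extra.append(g)
    for g1, g2 in pairs:
        name = f"{g1}:{g2}"
        design[name] = frame[g1] * frame[g2]
        extra.append(name)
    return design, basic_terms, extra


def compare_models(
    dataset: Dataset,
    genes: list[str],
    pairs: list[tuple[str, str]],
    config: PipelineConfig,
) -> list[AUCComparison]:
    """Basic vs optimized (covariates + genes) AUC at each configured horizon."""
    design, basic_terms, extra = _auc_design(dataset, genes, pairs, config)
    comparisons = []
    for horizon in config.horizons:
        comparisons.append(
            bootstrap_auc_compare(
                RiskModel("basic", basic_terms),
                RiskModel("optimized", basic_terms + extra),
                design,
                dataset.survival,
                horizon,
                n_boot=config.n_boot,
                seed=config._seed_for(3, int(horizon * 1000)),
            )
        )
    return comparisons


def run_validation(
    discovery_report: DiscoveryReport,
    validation: Dataset,
    config: PipelineConfig,
    stratify: bool = True,
) -> ValidationReport:
    """Execute the validation phase given discovery artifacts."""
    retained = discovery_report.retained
    discovery = discovery_report.dataset
    targets = discovery_report.significant_genes()
    disc_expr = _modelling_matrix(discovery.fpkm, config)
    surrogate_map = find_surrogates(
        targets, discovery.fpkm, validation.fpkm.gene_ids, config.q_discovery
    )
    verdicts = validate_terms(
        retained,
        surrogate_map,
        validation,
        p_threshold=config.p_validation,
        transform=config.transform == "log2p1",
    )

    strat_disc = strat_val = None
    if stratify and retained:
        strat_disc = stratified_analysis(
            retained, discovery, transform=config.transform == "log2p1"
        )
        surrogate_results = []
        for v in verdicts:
            if v.validation is not None:
                surrogate_results.append(v.validation)
        if surrogate_results:
            strat_val = stratified_analysis(
                surrogate_results, validation, transform=config.transform == "log2p1"
            )

    genes = [g for r in discovery_report.retained_main for g in r.genes]
    pairs = [r.genes for r in discovery_report.retained_interaction]
    for g1, g2 in pairs:
        for g in (g1, g2):
            if g not in genes:
                genes.append(g)
    comparisons = (
        compare_models(discovery, genes, pairs, config) if (genes or pairs) else []
    )

    manifest = build_manifest(config, discovery, validation)
    return ValidationReport(
        surrogate_map=surrogate_map,
        verdicts=verdicts,
        stratified_discovery=strat_disc,
        stratified_validation=strat_val,
        auc_comparisons=comparisons,
        manifest=manifest,
    )


def _hash_array(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()[:16]


def build_manifest(
    config: PipelineConfig, discovery: Dataset, validation: Dataset | None = None
) -> dict:
    import lifelines
    import scipy

    from . import __version__

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "seed": config.seed,
        "versions": {
            "lncsurv": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "lifelines": lifelines.__version__,
        },
        "inputs": {
            "discovery_fpkm": _hash_array(discovery.fpkm.values()),
            "discovery_survival": _hash_array(
                np.column_stack([discovery.survival.time, discovery.survival.event])
            ),
        },
    }
    if validation is not None:
        manifest["inputs"]["validation_fpkm"] = _hash_array(validation.fpkm.values())
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    return manifest


def write_discovery_artifacts(report: DiscoveryReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.gene_qc.to_csv(outdir / "gene_qc.csv", index=False)
    report.ranking.table.to_csv(outdir / "vis_ranking.csv", index=False)
    report.oob_curve.to_frame().to_csv(outdir / "oob_curve.csv", index=False)
    pd.Series(report.candidates, name="gene_id").to_csv(
        outdir / "candidates.csv", index=False
    )
    results_to_frame(report.main_fpkm).to_csv(outdir / "main_fpkm.csv", index=False)
    results_to_frame(report.main_tmm).to_csv(outdir / "main_tmm.csv", index=False)
    results_to_frame(report.interaction_fpkm).to_csv(
        outdir / "interaction_fpkm.csv", index=False
    )
    results_to_frame(report.interaction_tmm).to_csv(
        outdir / "interaction_tmm.csv", index=False
    )
    report.intersection_log.to_csv(outdir / "sensitivity_intersection.csv", index=False)
    with open(outdir / "stage_counts.json", "w") as fh:
        json.dump(report.stage_counts, fh, indent=2)


def write_validation_artifacts(report: ValidationReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.surrogate_map.to_frame().to_csv(outdir / "surrogate_map.csv", index=False)
    pd.DataFrame([v.to_dict() for v in report.verdicts]).to_csv(
        outdir / "verdicts.csv", index=False
    )
    if report.stratified_discovery is not None:
        report.stratified_discovery.to_csv(
            outdir / "stratified_discovery.csv", index=False
        )
    if report.stratified_validation is not None:
        report.stratified_validation.to_csv(
            outdir / "stratified_validation.csv", index=False
        )
    if report.auc_comparisons:
        pd.DataFrame([c.to_dict() for c in report.auc_comparisons]).to_csv(
            outdir / "auc_comparison.csv", index=False
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)
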