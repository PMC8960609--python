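"""Two-platform synthetic expression + clinical + survival data with known truth.

The generator emulates the statistical structure of a two-phase
expression–survival study:

* log-scale expression with block-correlated genes, so that every
  informative gene has correlated "surrogate" partners;
* a paired raw-count matrix (Poisson sampling of the same latent
  intensities with per-sample library-size multipliers) so both the
  FPKM-like and the count-normalization analysis branches can run;
* clinical covariates with marginals matching a large NSCLC discovery
  cohort (age 66.02 +/- 9.55, stage frequencies 54.3/28.3/14.6/2.8%, ...);
* survival times drawn from a Weibull-baseline Cox model whose linear
  predictor contains configured main effects, one optional gene-gene
  interaction (product of standardized expressions), and covariate
  effects; censoring is independent exponential, calibrated by
  root-finding so the realized censoring rate hits a target (59.60% by
  default);
* a second "platform" holding only a subset of genes, optionally forced
  to be missing the truth genes so the surrogate-validation path is
  exercised.

All gene effects are per standard deviation of log2 expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import DataError, Dataset, ExpressionMatrix, SurvivalOutcome

# Discovery-cohort clinical marginals (frequencies of a 604-patient NSCLC cohort)
DEFAULT_MEAN_AGE = 66.02
DEFAULT_SD_AGE = 9.55
DEFAULT_GENDER_PROPS = {"Male": 0.5877, "Female": 0.4123}
DEFAULT_RACE_PROPS = {"White": 0.8957, "Black": 0.0911, "Asian": 0.0132}
DEFAULT_SMOKE_PROPS = {"Former": 0.6887, "Current": 0.3113}
DEFAULT_STAGE_PROPS = {"I": 0.5430, "II": 0.2831, "III": 0.1457, "IV": 0.0281}
DEFAULT_HISTOLOGY_PROPS = {"LUAD": 0.4868, "LUSC": 0.5132}
DEFAULT_MEAN_PACK_YEARS = 47.38
DEFAULT_SD_PACK_YEARS = 29.96

#: Covariate effects on the hazard (log-HR per encoded design column; age per year)
DEFAULT_COVARIATE_LOG_HRS = {
    "age": 0.025,
    "clinical_stage_II": 0.40,
    "clinical_stage_III": 0.80,
    "clinical_stage_IV": 1.10,
    "gender_Male": 0.15,
}


class DegenerateSurvivalError(DataError):
    """All-event or all-censored survival draw."""


@dataclass
class SimulationConfig:
    """Ground-truth container for one simulated cohort.

    Gene effects (``main_log_hr``, ``interaction_log_hr``) apply to
    z-scored log2 expression, i.e. they are per-SD log hazard ratios.
    """

    n_subjects: int = 604
    n_genes: int = 100
    n_informative_main: int = 3
    main_log_hr: float | tuple[float, ...] = 0.5
    interaction_pair: tuple[int, int] | None = None
    interaction_log_hr: float = 0.6
    #: own (alpha1, alpha2) main effects of the interaction pair, per SD;
    #: defaults emulate a pair whose constituents are themselves prognostic
    #: (discovery-phase HRs ~0.69 and ~1.30)
    interaction_main_log_hrs: tuple[float, float] = (-0.37, 0.26)
    covariate_log_hrs: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LOG_HRS)
    )
    baseline_shape: float = 1.2
    baseline_scale: float = 5.3
    target_censoring_rate: float = 0.596
    platform_overlap_fraction: float = 0.7
    surrogate_correlation: float = 0.9
    block_size: int = 2
    seed: int = 0
    # clinical marginals
    mean_age: float = DEFAULT_MEAN_AGE
    sd_age: float = DEFAULT_SD_AGE
    gender_props: dict = field(default_factory=lambda: dict(DEFAULT_GENDER_PROPS))
    race_props: dict = field(default_factory=lambda: dict(DEFAULT_RACE_PROPS))
    smoke_props: dict = field(default_factory=lambda: dict(DEFAULT_SMOKE_PROPS))
    stage_props: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_PROPS))
    histology_props: dict = field(default_factory=lambda: dict(DEFAULT_HISTOLOGY_PROPS))
    mean_pack_years: float = DEFAULT_MEAN_PACK_YEARS
    sd_pack_years: float = DEFAULT_SD_PACK_YEARS
    # expression/count nuisance parameters
    gene_mean_loc: float = 2.5
    gene_mean_scale: float = 0.8
    library_size_sd: float = 0.3
    #: reads per unit FPKM-like intensity; the default puts a few hundred
    #: reads on a typically expressed gene, so Poisson measurement noise is
    #: small relative to biological variation (as in deeply sequenced bulk
    #: libraries) and the count branch is a normalization sensitivity check
    #: rather than a separate, noisier assay
    count_depth: float = 50.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.n_genes < 1 or self.block_size < 1:
            raise ValueError("n_genes and block_size must be positive")
        if self.n_informative_main < 0:
            raise ValueError("n_informative_main must be non-negative")
        if not 0.0 < self.target_censoring_rate < 1.0:
            raise ValueError("target_censoring_rate must lie strictly in (0, 1)")
        if not 0.0 < self.platform_overlap_fraction <= 1.0:
            raise ValueError("platform_overlap_fraction must lie in (0, 1]")
        if not 0.0 < self.surrogate_correlation < 1.0:
            raise ValueError("surrogate_correlation must lie in (0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull baseline parameters must be positive")
        if self.interaction_pair is not None:
            a, b = self.interaction_pair
            if a == b or not (0 <= a < self.n_genes and 0 <= b < self.n_genes):
                raise ValueError("interaction_pair must be two distinct gene indices")
        if np.isscalar(self.main_log_hr):
            self.main_log_hr = tuple([float(self.main_log_hr)] * self.n_informative_main)
        else:
            self.main_log_hr = tuple(float(v) for v in self.main_log_hr)
            if len(self.main_log_hr) != self.n_informative_main:
                raise ValueError("main_log_hr length must equal n_informative_main")
        for props in (
            self.gender_props,
            self.race_props,
            self.smoke_props,
            self.stage_props,
            self.histology_props,
        ):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-3:
                raise ValueError(f"categorical proportions sum to {total}, not 1")

    # -- ground-truth gene placement ------------------------------------
    @property
    def informative_indices(self) -> list[int]:
        """Informative main-effect genes: one per block, starting at block 0."""
        idx = [i * self.block_size for i in range(self.n_informative_main)]
        if idx and idx[-1] >= self.n_genes:
            raise ValueError("too many informative genes for n_genes/block_size")
        return idx

    @property
    def interaction_indices(self) -> tuple[int, int] | None:
        """Interaction pair: configured, or the two blocks after the main genes."""
        if self.interaction_pair is not None:
            return self.interaction_pair
        if self.interaction_log_hr == 0.0:
            return None
        a = self.n_informative_main * self.block_size
        b = a + self.block_size
        if b >= self.n_genes:
            raise ValueError("n_genes too small to place the interaction pair")
        return (a, b)

    def gene_id(self, index: int) -> str:
        return f"G{index:04d}"


@dataclass
class SyntheticTruth:
    """What was planted, in terms of generated gene ids."""

    informative_gene_ids: list[str]
    main_log_hrs: dict[str, float]
    interaction_pair_ids: tuple[str, str] | None
    interaction_log_hr: float
    interaction_main_log_hrs: tuple[float, float]
    covariate_log_hrs: dict[str, float]
    discovery_genes: list[str]
    validation_genes: list[str]
    block_partners: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "informative_gene_ids": self.informative_gene_ids,
            "main_log_hrs": self.main_log_hrs,
            "interaction_pair_ids": list(self.interaction_pair_ids)
            if self.interaction_pair_ids
            else None,
            "interaction_log_hr": self.interaction_log_hr,
            "interaction_main_log_hrs": list(self.interaction_main_log_hrs),
            "covariate_log_hrs": self.covariate_log_hrs,
            "discovery_genes": self.discovery_genes,
            "validation_genes": self.validation_genes,
            "block_partners": self.block_partners,
        }


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    """Counter-based substream so each stage is independently reproducible."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


def _draw_categorical(rng, props: dict[str, float], n: int) -> np.ndarray:
    levels = sorted(props)
    p = np.array([props[l] for l in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def simulate_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Clinical covariate table with the configured marginals; no missing values."""
    rng = rng if rng is not None else _rng(config, 1)
    n = config.n_subjects
    age = rng.normal(config.mean_age, config.sd_age, size=n)
    if config.sd_pack_years > 0:
        a = -config.mean_pack_years / config.sd_pack_years
        pack = stats.truncnorm.rvs(
            a, np.inf, loc=config.mean_pack_years, scale=config.sd_pack_years,
            size=n, random_state=rng,
        )
    else:
        pack = np.full(n, config.mean_pack_years)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "age": age,
            "gender": _draw_categorical(rng, config.gender_props, n),
            "race": _draw_categorical(rng, config.race_props, n),
            "smoke_status": _draw_categorical(rng, config.smoke_props, n),
            "pack_years": pack,
            "clinical_stage": _draw_categorical(rng, config.stage_props, n),
            "histology": _draw_categorical(rng, config.histology_props, n),
        }
    )


def _gene_block_slices(config: SimulationConfig) -> list[slice]:
    edges = list(range(0, config.n_genes, config.block_size)) + [config.n_genes]
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _gene_means(config: SimulationConfig) -> np.ndarray:
    # gene-level parameters come from a gene stream so that several cohorts
    # simulated from the same config share the expression landscape
    rng = _rng(config, 0)
    return rng.normal(config.gene_mean_loc, config.gene_mean_scale, size=config.n_genes)


def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Draw (counts, fpkm_like) matrices for one cohort.

    Latent log2 expression is blockwise-equicorrelated Gaussian (within a
    block, correlation = ``surrogate_correlation``); the FPKM-like matrix
    is its exponential (log-normal, strictly positive); counts are Poisson
    draws of the FPKM intensities scaled by per-sample library-size
    multipliers.
    """
    rho = config.surrogate_correlation
    if not -1.0 / max(config.block_size - 1, 1) < rho < 1.0:
        raise DataError("block correlation is not positive definite")
    rng = rng if rng is not None else _rng(config, 2)
    n, g = config.n_subjects, config.n_genes
    z = rng.standard_normal((n, g))
    latent = np.empty((n, g))
    for block in _gene_block_slices(config):
        k = block.stop - block.start
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
        latent[:, block] = z[:, block] @ np.linalg.cholesky(corr).T
    latent = latent + _gene_means(config)[None, :]

    gene_ids = [config.gene_id(i) for i in range(g)]
    sample_ids = [f"S{i:05d}" for i in range(n)]
    fpkm = 2.0 ** latent  # genes on rows after transpose below
    lib_mult = np.exp(rng.normal(0.0, config.library_size_sd, size=n))
    intensity = fpkm * config.count_depth * lib_mult[:, None]
    counts = rng.poisson(intensity).astype(float)
    fpkm_m = ExpressionMatrix(
        pd.DataFrame(fpkm.T, index=gene_ids, columns=sample_ids), "fpkm"
    )
    counts_m = ExpressionMatrix(
        pd.DataFrame(counts.T, index=gene_ids, columns=sample_ids), "counts"
    )
    return counts_m, fpkm_m


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - values.mean(axis=0)) / sd


def covariate_design_for_truth(clinical: pd.DataFrame) -> pd.DataFrame:
    """Encoded covariates on the scale the truth coefficients refer to."""
    from .design import encode_covariates

    return encode_covariates(clinical)


def simulate_survival(
    fpkm: ExpressionMatrix,
    clinical: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SurvivalOutcome:
    """Cox-model survival times with calibrated independent censoring.

    The linear predictor uses z-scored log2 expression for the gene terms
    (so configured log-HRs are per SD) and the encoded clinical covariates.
    Event times come from the Weibull-baseline inverse transform
    T = scale * (-log U / exp(lp))^(1/shape); censoring is exponential with
    a scale found by root-finding so the realized censoring rate matches
    ``target_censoring_rate``.
    """
    if fpkm.sample_ids != clinical["sample_id"].tolist():
        raise DataError("expression and clinical tables are not sample-aligned")
    rng = rng if rng is not None else _rng(config, 3)
    n = fpkm.n_samples
    log_expr = np.log2(fpkm.values().T)  # samples x genes
    z = _standardize(log_expr)

    lp = np.zeros(n)
    for idx, beta in zip(config.informative_indices, config.main_log_hr):
        lp += beta * z[:, idx]
    pair = config.interaction_indices
    if pair is not None:
        a1, a2 = config.interaction_main_log_hrs
        lp += a1 * z[:, pair[0]] + a2 * z[:, pair[1]]
        lp += config.interaction_log_hr * z[:, pair[0]] * z[:, pair[1]]
    design = covariate_design_for_truth(clinical)
    for name, beta in config.covariate_log_hrs.items():
        if beta == 0.0 or name not in design.columns:
            continue
        col = design[name].to_numpy(dtype=float)
        if name in ("age", "pack_years"):
            col = col - col.mean()
        lp += beta * col

    u = rng.uniform(size=n)
    event_time = config.baseline_scale * (-np.log(u) / np.exp(lp)) ** (
        1.0 / config.baseline_shape
    )
    cens_draw = -np.log(rng.uniform(size=n))

    target = config.target_censoring_rate

    def censoring_gap(scale: float) -> float:
        return float(np.mean(event_time > scale * cens_draw)) - target

    lo, hi = 1e-8, 1e8
    if censoring_gap(lo) < 0 or censoring_gap(hi) > 0:
        raise DegenerateSurvivalError("censoring rate target unreachable for this draw")
    cens_scale = optimize.brentq(censoring_gap, lo, hi, xtol=1e-12)
    cens_time = cens_scale * cens_draw
    observed = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    if event.sum() == 0 or event.sum() == n:
        raise DegenerateSurvivalError(
            f"degenerate survival draw: {event.sum()} events of {n}"
        )
    return SurvivalOutcome(fpkm.sample_ids, np.maximum(observed, 1e-8), event)


def _truth_gene_ids(config: SimulationConfig) -> list[str]:
    ids = [config.gene_id(i) for i in config.informative_indices]
    pair = config.interaction_indices
    if pair is not None:
        ids += [config.gene_id(i) for i in pair]
    return ids


def _block_partner_map(config: SimulationConfig) -> dict[str, list[str]]:
    partners: dict[str, list[str]] = {}
    for block in _gene_block_slices(config):
        members = [config.gene_id(i) for i in range(block.start, block.stop)]
        for g in members:
            partners[g] = [m for m in members if m != g]
    return partners


def split_platforms(
    fpkm: ExpressionMatrix,
    config: SimulationConfig,
    force_missing: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Restrict a cohort to the validation platform's gene subset.

    The validation platform keeps exactly floor(overlap * n_genes) genes.
    With ``force_missing`` every truth gene is dropped (so validation must
    go through surrogates) while its block partners are guaranteed kept.
    Raises if the overlap leaves no room for the surrogate partners.
    """
    rng = rng if rng is not None else _rng(config, 4)
    all_genes = fpkm.gene_ids
    n_keep = int(np.floor(config.platform_overlap_fraction * len(all_genes)))
    truth_genes = _truth_gene_ids(config)
    partners = _block_partner_map(config)
    truth_partners = sorted({p for g in truth_genes for p in partners.get(g, [])})

    if not force_missing:
        if n_keep == len(all_genes):
            kept = list(all_genes)
        else:
            kept = sorted(rng.choice(all_genes, size=n_keep, replace=False).tolist())
    else:
        if n_keep < len(truth_partners) or not truth_partners:
            raise DataError(
                "platform overlap too low: no surrogate block would survive"
            )
        n_drop = len(all_genes) - n_keep
        if n_drop < len(truth_genes):
            raise DataError(
                "platform overlap too high to force all truth genes off the platform"
            )
        pool = [g for g in all_genes if g not in truth_genes and g not in truth_partners]
        extra = n_drop - len(truth_genes)
        if extra > len(pool):
            raise DataError("platform overlap too low: surrogate blocks would be lost")
        dropped = set(truth_genes) | set(
            rng.choice(pool, size=extra, replace=False).tolist()
        )
        kept = [g for g in all_genes if g not in dropped]

    truth = SyntheticTruth(
        informative_gene_ids=[config.gene_id(i) for i in config.informative_indices],
        main_log_hrs={
            config.gene_id(i): b
            for i, b in zip(config.informative_indices, config.main_log_hr)
        },
        interaction_pair_ids=(
            tuple(config.gene_id(i) for i in config.interaction_indices)
            if config.interaction_indices is not None
            else None
        ),
        interaction_log_hr=config.interaction_log_hr,
        interaction_main_log_hrs=tuple(config.interaction_main_log_hrs),
        covariate_log_hrs=dict(config.covariate_log_hrs),
        discovery_genes=list(all_genes),
        validation_genes=kept,
        block_partners=partners,
    )
    return fpkm, fpkm.subset_genes(kept), truth


def simulate_dataset(
    config: SimulationConfig, name: str = "cohort", id_prefix: str = "S"
) -> Dataset:
    """One aligned cohort (counts + FPKM + clinical + survival)."""
    clinical = simulate_covariates(config)
    counts, fpkm = simulate_expression(config)
    outcome = simulate_survival(fpkm, clinical, config)
    if id_prefix != "S":
        mapping = {s: id_prefix + s[1:] for s in fpkm.sample_ids}
        fpkm = ExpressionMatrix(fpkm.data.rename(columns=mapping), fpkm.unit)
        counts = ExpressionMatrix(counts.data.rename(columns=mapping), counts.unit)
        clinical = clinical.assign(sample_id=clinical["sample_id"].map(mapping))
        outcome = SurvivalOutcome(
            [mapping[s] for s in outcome.sample_ids], outcome.time, outcome.event
        )
    return Dataset(fpkm=fpkm, clinical=clinical, survival=outcome, counts=counts, name=name)


def simulate_two_phase(
    config: SimulationConfig,
    n_validation: int = 839,
    validation_censoring_rate: float = 0.5566,
    force_missing: bool = True,
) -> tuple[Dataset, Dataset, SyntheticTruth]:
    """Discovery + validation cohorts sharing the gene landscape and truth.

    The validation cohort is an independent subject draw from the same
    generating model (different sample size and censoring rate, matching a
    typical validation-phase cohort), restricted to the validation
    platform's gene subset.
    """
    discovery = simulate_dataset(config, name="discovery", id_prefix="D")
    val_config = SimulationConfig(
        **{
            **config.__dict__,
            "n_subjects": n_validation,
            "target_censoring_rate": validation_censoring_rate,
            "seed": config.seed,
            "main_log_hr": config.main_log_hr,
        }
    )
    # independent subject-level draws for the validation cohort
    clinical = simulate_covariates(val_config, _rng(config, 11))
    counts, fpkm = simulate_expression(val_config, _rng(config, 12))
    outcome = simulate_survival(fpkm, clinical, val_config, _rng(config, 13))
    _, val_fpkm, truth = split_platforms(fpkm, config, force_missing, _rng(config, 14))
    val_counts = counts.subset_genes(val_fpkm.gene_ids)

    mapping = {s: "V" + s[1:] for s in val_fpkm.sample_ids}
    val_fpkm = ExpressionMatrix(val_fpkm.data.rename(columns=mapping), "fpkm")
    val_counts = ExpressionMatrix(val_counts.data.rename(columns=mapping), "counts")
    clinical = clinical.assign(sample_id=clinical["sample_id"].map(mapping))
    outcome = SurvivalOutcome(
        [mapping[s] for s in outcome.sample_ids], outcome.time, outcome.event
    )
    validation = Dataset(
        fpkm=val_fpkm, clinical=clinical, survival=outcome, counts=val_counts,
        name="validation",
    )
    return discovery, validation, truth
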