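"""Synthetic multi-cohort data with the structure the pipeline assumes.

The generator emulates the three cohort roles of a blood-expression
prognostic study, plus platform-shifted validation views:

* two unlabelled *reference* cohorts sharing planted co-expression modules
  (one latent factor per module; loadings sqrt(r) give expected pairwise
  within-module correlation r);
* one labelled *training* cohort in which prognostic-module genes are
  shifted by a log2 effect size between high- and low-risk groups, with
  exponential survival whose hazard is multiplied by exp(log-HR) for the
  high-risk group and independent exponential censoring;
* *validation* cohorts re-expressed through per-gene affine platform
  distortions: RNA-seq (gain ≈ 1, offset ≈ 0, noise) and qPCR delta-Ct
  (delta_ct = a − b·expression + noise with b > 0, so lower Ct means more
  transcript).

Each planted module's first gene is its *driver*: its effect size is
boosted and its baseline abundance raised above the transcriptome median,
so the representative-gene stage has a well-defined ground truth.

All randomness flows from the single config seed (one spawned stream per
cohort role), so identical configs give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import (MICROARRAY, QPCR, RNASEQ, ExpressionMatrix, GeneSetCollection,
                 PhenotypeTable)

_ROLE_STREAM = {"reference_1": 0, "reference_2": 1, "training": 2,
                "validation": 3, "genesets": 4}


@dataclass
class ModuleSpec:
    """One planted co-expression module."""

    name: str
    size: int = 30
    direction: str = "null"        # up / down / null
    within_correlation: float = 0.7
    effect_size: float = 0.0       # mean high−low shift (log2) in training
    shared: bool = True            # planted in both reference cohorts?

    def __post_init__(self):
        if self.size < 5:
            raise ConfigError(f"module {self.name}: size must be >= 5")
        if not (0 <= self.within_correlation < 1):
            raise ConfigError(
                f"module {self.name}: within_correlation must be in [0, 1)")
        if self.direction not in ("up", "down", "null"):
            raise ConfigError(f"module {self.name}: bad direction")
        if self.direction == "up" and self.effect_size < 0:
            raise ConfigError(f"module {self.name}: up module needs effect >= 0")
        if self.direction == "down" and self.effect_size > 0:
            raise ConfigError(f"module {self.name}: down module needs effect <= 0")
        if self.direction == "null" and self.effect_size != 0:
            raise ConfigError(f"module {self.name}: null module needs effect 0")


@dataclass
class AffinePlatformMap:
    """Per-gene affine distortion applied to the latent expression."""

    gain_mean: float = 1.0
    gain_sd: float = 0.1
    offset_mean: float = 0.0
    offset_sd: float = 0.5
    noise_sd: float = 0.2
    negate: bool = False  # qPCR delta-Ct convention: value = offset − gain·x


def _default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec("up_module_1", 30, "up", 0.7, 1.5, True),
        ModuleSpec("up_module_2", 30, "up", 0.7, 1.2, True),
        ModuleSpec("down_module_1", 30, "down", 0.7, -1.5, True),
        ModuleSpec("down_module_2", 30, "down", 0.7, -1.2, True),
        ModuleSpec("coexp_only", 30, "null", 0.7, 0.0, True),
        ModuleSpec("unstable_up", 30, "up", 0.7, 1.2, False),
    ]


def _default_platform_maps() -> dict:
    return {
        RNASEQ: AffinePlatformMap(),
        QPCR: AffinePlatformMap(gain_mean=1.0, gain_sd=0.1,
                                offset_mean=18.0, offset_sd=2.0,
                                noise_sd=0.2, negate=True),
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic multi-cohort experiment."""

    n_genes: int = 800
    module_specs: list[ModuleSpec] = field(default_factory=_default_modules)
    n_reference_1: int = 200
    n_reference_2: int = 200
    n_train_high: int = 30
    n_train_low: int = 30
    n_validation: int = 25
    baseline_hazard: float = math.log(2) / 24.0   # median ~24 months, low risk
    log_hr: float = math.log(3.0)                 # planted hazard ratio 3
    censoring_rate: float = 1.0 / 120.0
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    driver_boost: float = 1.5
    platform_maps: dict = field(default_factory=_default_platform_maps)
    seed: int = 0

    def __post_init__(self):
        for n in (self.n_reference_1, self.n_reference_2, self.n_train_high,
                  self.n_train_low, self.n_validation, self.n_genes):
            if n <= 0:
                raise ConfigError("all counts must be positive")
        if sum(m.size for m in self.module_specs) > self.n_genes:
            raise ConfigError("module sizes exceed n_genes")
        names = [m.name for m in self.module_specs]
        if len(set(names)) != len(names):
            raise ConfigError("module names must be unique")

    # -- gene bookkeeping ---------------------------------------------------
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def module_genes(self, name: str) -> list[str]:
        start = 0
        for spec in self.module_specs:
            if spec.name == name:
                return [f"G{i:04d}" for i in range(start, start + spec.size)]
            start += spec.size
        raise KeyError(name)

    def driver_gene(self, name: str) -> str:
        return self.module_genes(name)[0]

    def prognostic_modules(self) -> list[ModuleSpec]:
        return [m for m in self.module_specs if m.effect_size != 0 and m.shared]

    def driver_genes(self) -> list[str]:
        return [self.driver_gene(m.name) for m in self.prognostic_modules()]

    def manifest(self) -> dict:
        return {"seed": self.seed, "config": asdict(self)}

    def _rng(self, role: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_ROLE_STREAM))
        return np.random.default_rng(children[_ROLE_STREAM[role]])


def _baselines(config: SimulationConfig) -> pd.Series:
    """Deterministic per-gene baseline abundances; drivers forced abundant."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).entropy % (2**31))
    base = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    base = pd.Series(base, index=config.gene_ids())
    for spec in config.module_specs:
        base.loc[config.driver_gene(spec.name)] = \
            config.baseline_mean + 2.0 * config.baseline_sd
    return base


def _latent_matrix(config: SimulationConfig, rng: np.random.Generator,
                   n_samples: int, active_modules: list[ModuleSpec]
                   ) -> np.ndarray:
    """Factor-model expression: gene = baseline + sqrt(r)·f + sqrt(1−r)·eps.

    Module factors and residuals are scaled by noise_sd so every gene has
    marginal sd ≈ noise_sd and within-module pairwise correlation ≈ r.
    """
    X = rng.normal(0.0, 1.0, size=(config.n_genes, n_samples))
    gene_index = {g: i for i, g in enumerate(config.gene_ids())}
    for spec in active_modules:
        r = spec.within_correlation
        if r == 0:
            continue
        factor = rng.normal(0.0, 1.0, size=n_samples)
        rows = [gene_index[g] for g in config.module_genes(spec.name)]
        X[rows] = math.sqrt(r) * factor + math.sqrt(1 - r) * X[rows]
    X *= config.noise_sd
    X += _baselines(config).to_numpy()[:, None]
    return X


def simulate_reference_cohort(config: SimulationConfig,
                              which: int) -> ExpressionMatrix:
    """One unlabelled reference cohort; unshared modules appear only in cohort 1."""
    if which not in (1, 2):
        raise ConfigError("which must be 1 or 2")
    role = f"reference_{which}"
    rng = config._rng(role)
    n = config.n_reference_1 if which == 1 else config.n_reference_2
    active = [m for m in config.module_specs if m.shared or which == 1]
    X = _latent_matrix(config, rng, n, active)
    samples = [f"R{which}_S{i:03d}" for i in range(n)]
    df = pd.DataFrame(X, index=config.gene_ids(), columns=samples)
    return ExpressionMatrix(df, platform=MICROARRAY,
                            scale_note=f"synthetic reference cohort {which}")


def _effect_vector(config: SimulationConfig) -> pd.Series:
    eff = pd.Series(0.0, index=config.gene_ids())
    for spec in config.module_specs:
        if spec.effect_size == 0:
            continue
        genes = config.module_genes(spec.name)
        eff.loc[genes] = spec.effect_size
        eff.loc[genes[0]] = spec.effect_size * config.driver_boost
    return eff


def _survival_times(rng: np.random.Generator, risk: np.ndarray,
                    config: SimulationConfig):
    """Exponential survival with hazard h0·exp(log_hr·risk), exp. censoring."""
    hazard = config.baseline_hazard * np.exp(config.log_hr * risk)
    death = rng.exponential(1.0 / hazard)
    censor = rng.exponential(1.0 / config.censoring_rate, size=risk.size)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    return time, event


def _labelled_cohort(config: SimulationConfig, rng: np.random.Generator,
                     n_high: int, n_low: int, prefix: str):
    n = n_high + n_low
    risk = np.array([1] * n_high + [0] * n_low)
    X = _latent_matrix(config, rng, n, list(config.module_specs))
    X += np.outer(_effect_vector(config).to_numpy(), risk)
    time, event = _survival_times(rng, risk.astype(float), config)
    samples = [f"{prefix}_S{i:03d}" for i in range(n)]
    expr = ExpressionMatrix(pd.DataFrame(X, index=config.gene_ids(),
                                         columns=samples),
                            platform=MICROARRAY,
                            scale_note=f"synthetic {prefix} cohort")
    pheno = PhenotypeTable(pd.DataFrame({
        "risk_label": np.where(risk == 1, "high", "low"),
        "survival_time": np.round(time, 3),
        "event": event,
    }, index=pd.Index(samples, name="sample_id")))
    return expr, pheno


def simulate_training_cohort(config: SimulationConfig
                             ) -> tuple[ExpressionMatrix, PhenotypeTable]:
    """Labelled training cohort with group-shifted module genes and survival."""
    rng = config._rng("training")
    return _labelled_cohort(config, rng, config.n_train_high,
                            config.n_train_low, "TR")


def simulate_validation_cohort(config: SimulationConfig, platform: str,
                               return_latent: bool = False):
    """Validation cohort re-expressed through a platform distortion.

    The latent cohort is drawn like the training cohort (half high risk),
    then each gene is passed through the platform's per-gene affine map
    plus measurement noise; the qPCR map is negated (delta-Ct convention).
    """
    if platform not in config.platform_maps:
        raise ConfigError(f"unknown platform {platform!r}")
    pmap: AffinePlatformMap = config.platform_maps[platform]
    rng = config._rng("validation")
    n_high = config.n_validation // 2
    n_low = config.n_validation - n_high
    latent, pheno = _labelled_cohort(config, rng, n_high, n_low, "VA")
    gains = rng.normal(pmap.gain_mean, pmap.gain_sd, config.n_genes)
    offsets = rng.normal(pmap.offset_mean, pmap.offset_sd, config.n_genes)
    noise = rng.normal(0.0, pmap.noise_sd,
                       size=(config.n_genes, config.n_validation)) \
        if pmap.noise_sd > 0 else 0.0
    sign = -1.0 if pmap.negate else 1.0
    values = offsets[:, None] + sign * gains[:, None] * latent.values.to_numpy()
    values = values + noise
    distorted = ExpressionMatrix(
        pd.DataFrame(values, index=latent.values.index,
                     columns=latent.values.columns),
        platform=platform, scale_note=f"synthetic validation view ({platform})")
    if return_latent:
        return distorted, pheno, latent
    return distorted, pheno


def simulate_gene_set_collections(config: SimulationConfig
                                  ) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Pathway and cell-type GMT collections aligned with the planted modules.

    Each module gets one "pathway" (its genes plus random extras) and each
    direction one cell-type signature (myeloid for up, lymphoid for down),
    plus decoy sets of random genes, so the annotation stage has a planted
    ground truth with realistic negatives.
    """
    rng = config._rng("genesets")
    genes = config.gene_ids()
    pathways: dict[str, list[str]] = {}
    celltypes: dict[str, list[str]] = {}
    for spec in config.module_specs:
        members = config.module_genes(spec.name)
        extras = list(rng.choice(genes, size=20, replace=False))
        pathways[f"PATHWAY_{spec.name.upper()}"] = \
            list(dict.fromkeys(members + extras))
    for i in range(4):
        pathways[f"PATHWAY_DECOY_{i}"] = \
            list(rng.choice(genes, size=40, replace=False))
    up_genes = [g for m in config.module_specs if m.direction == "up"
                for g in config.module_genes(m.name)]
    down_genes = [g for m in config.module_specs if m.direction == "down"
                  for g in config.module_genes(m.name)]
    if up_genes:
        celltypes["MYELOID_OVEREXPRESSED"] = list(dict.fromkeys(
            up_genes + list(rng.choice(genes, size=15, replace=False))))
    if down_genes:
        celltypes["LYMPHOID_OVEREXPRESSED"] = list(dict.fromkeys(
            down_genes + list(rng.choice(genes, size=15, replace=False))))
    for name in ("ERYTHROID", "MEGAKARYOCYTE", "GRANULOCYTE"):
        celltypes[f"{name}_OVEREXPRESSED"] = \
            list(rng.choice(genes, size=30, replace=False))
    return (GeneSetCollection(pathways, source_note="synthetic pathways"),
            GeneSetCollection(celltypes, source_note="synthetic cell types"))
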