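"""End-to-end orchestration of the module-based prognostic pipeline.

``run_study`` wires the five stages together on one training cohort plus
two reference cohorts:

1. moderated-t differential expression (high vs low risk), BH FDR < 0.05;
2. co-expression module detection per direction per reference cohort;
3. cross-cohort stability calling (Fisher p < 0.01) and up/down balancing;
4. functional-core extraction and representative-gene selection;
5. naïve-Bayes training with LOO-CV model-size selection.

``run_synthetic_study`` additionally generates every input from a
:class:`~bloodsig.simulate.SimulationConfig` and evaluates the final model
on a median/MAD-calibrated validation view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import annotation, crossplatform, diffexp, model, stability, survival
from .coexpression import NetworkParams, detect_modules
from .io import ExpressionMatrix, GeneSetCollection, PhenotypeTable, RNASEQ
from .simulate import (SimulationConfig, simulate_gene_set_collections,
                       simulate_reference_cohort, simulate_training_cohort,
                       simulate_validation_cohort)


@dataclass
class StudyResult:
    """Everything the pipeline produced, stage by stage."""

    de_table: pd.DataFrame
    up_candidates: list[str]
    down_candidates: list[str]
    stable_up: list
    stable_down: list
    cores: list
    up_representatives: list
    down_representatives: list
    k_pairs: int
    nb_model: object
    cv_performance: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_study(training: ExpressionMatrix, phenotype: PhenotypeTable,
              reference_1: ExpressionMatrix, reference_2: ExpressionMatrix,
              pathways: GeneSetCollection, celltypes: GeneSetCollection,
              fdr_cutoff: float = 0.05, network_params: NetworkParams | None = None,
              stability_alpha: float = 0.01,
              core_p_threshold: float = annotation.CORE_P_THRESHOLD
              ) -> StudyResult:
    params = network_params or NetworkParams()
    de = diffexp.moderated_t_test(training, phenotype)
    up, down = diffexp.select_candidates(de, fdr_cutoff)

    stable: dict[str, list] = {}
    for direction, candidates in (("up", up), ("down", down)):
        present = [g for g in candidates
                   if g in reference_1.values.index
                   and g in reference_2.values.index]
        if len(present) < params.min_module_size:
            stable[direction] = []
            continue
        a1 = detect_modules(reference_1, present, params,
                            dataset_tag="ref1", direction_tag=direction)
        a2 = detect_modules(reference_2, present, params,
                            dataset_tag="ref2", direction_tag=direction)
        if not a1.module_names() or not a2.module_names():
            stable[direction] = []
            continue
        overlaps = stability.overlap_table(a1, a2)
        stable[direction] = stability.call_stable_modules(
            overlaps, alpha=stability_alpha, direction=direction)
    stable_up, stable_down = stability.balance_directions(
        stable["up"], stable["down"])

    universe = set(training.gene_ids)
    cores, up_reps, down_reps = [], [], []
    for mod in stable_up + stable_down:
        core = annotation.functional_core(mod, pathways, celltypes, universe,
                                          p_threshold=core_p_threshold)
        cores.append(core)
        rep = model.select_representative(core, de, training)
        (up_reps if mod.direction == "up" else down_reps).append(rep)

    if not up_reps or not down_reps:
        return StudyResult(de, up, down, stable_up, stable_down, cores,
                           up_reps, down_reps, 0, None,
                           pd.DataFrame(), {"no_model": True})
    k, nb, perf = model.loocv_select(training, phenotype, phenotype,
                                     up_reps, down_reps)
    return StudyResult(de, up, down, stable_up, stable_down, cores,
                       up_reps, down_reps, k, nb, perf)


def run_synthetic_study(config: SimulationConfig,
                        validation_platform: str = RNASEQ) -> StudyResult:
    """Generate all cohorts from ``config`` and run the full pipeline.

    The result's ``extras`` carries the synthetic inputs, the calibrated
    validation scores and their survival evaluation, plus the latent-view
    scores for calibration-fidelity checks.
    """
    training, phenotype = simulate_training_cohort(config)
    ref1 = simulate_reference_cohort(config, 1)
    ref2 = simulate_reference_cohort(config, 2)
    pathways, celltypes = simulate_gene_set_collections(config)
    result = run_study(training, phenotype, ref1, ref2, pathways, celltypes)
    result.extras.update(training=training, phenotype=phenotype,
                         ref1=ref1, ref2=ref2, config=config)
    if result.nb_model is None:
        return result

    genes = result.nb_model.genes
    val_view, val_pheno, val_latent = simulate_validation_cohort(
        config, validation_platform, return_latent=True)
    cmap = crossplatform.fit_calibration(training, val_view, genes)
    calibrated = crossplatform.apply_calibration(cmap, val_view)
    scores = model.score_samples(result.nb_model, calibrated.subset_genes(genes))
    latent_scores = model.score_samples(result.nb_model,
                                        val_latent.subset_genes(genes))
    report = survival.evaluate_score(scores, val_pheno,
                                     cutoff=result.nb_model.cutoff)
    result.extras.update(validation_view=val_view, validation_pheno=val_pheno,
                         validation_latent=val_latent, calibration_map=cmap,
                         validation_scores=scores,
                         latent_scores=latent_scores,
                         validation_report=report)
    return result
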