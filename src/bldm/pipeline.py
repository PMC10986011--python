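"""End-to-end orchestration: reads -> blocks -> metrics -> markers -> model -> report.

The stages follow the frozen-discovery discipline: blocks are called on reads
pooled over discovery samples only, the marker funnel and all fitted state
(imputation reference, standardization, forest, threshold) are derived on
discovery, and validation/test cohorts are scored strictly through the frozen
:class:`~bldm.model.ModelBundle`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from bldm._sites import SiteIndex
from bldm.blocks import (
    DEFAULT_MAX_GAP_BP,
    DEFAULT_MIN_CPGS,
    DEFAULT_MIN_PAIRS,
    DEFAULT_R2_MIN,
    MHB,
    call_mhbs,
)
from bldm.io import Cohort, CpGSite
from bldm.metrics import MetricMatrix, build_metric_matrix
from bldm.model import (
    DiagnosticMetrics,
    ModelBundle,
    auc_ci,
    config_digest,
    confusion_from_calls,
    confusion_metrics,
    derive_threshold,
    roc_auc,
    score,
    standardize,
    subgroup_report,
    train_forest,
    ultrasound_comparator,
)
from bldm.selection import (
    DEFAULT_ALPHA,
    DEFAULT_KNN_K,
    DEFAULT_MIN_COV,
    DEFAULT_MAX_COV,
    DEFAULT_MIN_FRAC,
    MarkerSet,
    ScreenResult,
    filter_blocks_by_coverage,
    impute_missing_knn,
    rfecv_select,
    screen_markers,
)

logger = logging.getLogger(__name__)


@dataclass
class CohortEvaluation:
    """Scores, calls and the diagnostic battery for one evaluation cohort."""

    sample_ids: list[str]
    scores: np.ndarray
    calls: np.ndarray
    labels: list[str]
    metrics: DiagnosticMetrics
    comparator_metrics: DiagnosticMetrics | None
    subgroups: dict[str, DiagnosticMetrics | None]


@dataclass
class PipelineResult:
    mhbs: list[MHB]
    metric_matrix: MetricMatrix
    retained_blocks: list[str]
    screen_results: list[ScreenResult]
    marker_set: MarkerSet
    bundle: ModelBundle
    fold_thresholds: list[float]
    evaluations: dict[str, CohortEvaluation] = field(default_factory=dict)


def _marker_frame(matrix: MetricMatrix, sample_ids: Sequence[str], columns) -> pd.DataFrame:
    sub = matrix.values.loc[list(sample_ids)]
    return sub[[tuple(c) for c in columns]]


def evaluate_cohort(
    bundle: ModelBundle,
    matrix: MetricMatrix,
    cohort: Cohort,
    cohort_name: str,
    ci_seed: int = 0,
) -> CohortEvaluation:
    """Score one cohort through a frozen bundle and compute the full battery."""
    metas = cohort.split(cohort_name)
    ids = [m.sample_id for m in metas]
    features = _marker_frame(matrix, ids, bundle.marker_set.markers)
    scores = score(bundle, features)
    calls = scores >= bundle.threshold
    labels = [m.label for m in metas]
    y_known = [lab is not None for lab in labels]
    if not all(y_known):
        raise ValueError(f"cohort {cohort_name}: all samples need labels for evaluation")

    cc = confusion_from_calls(calls, labels)
    dm = confusion_metrics(cc)
    dm.auc = roc_auc(scores, labels)
    dm.auc_ci = auc_ci(scores, labels, seed=ci_seed)

    us_calls = ultrasound_comparator(metas)
    comp = None
    if us_calls:
        comp_ids = [i for i in ids if i in us_calls]
        comp_labels = [cohort.meta(i).label for i in comp_ids]
        comp = confusion_metrics(confusion_from_calls([us_calls[i] for i in comp_ids], comp_labels))

    score_map = dict(zip(ids, scores))
    call_map = dict(zip(ids, calls.tolist()))
    subgroups = subgroup_report(score_map, call_map, metas, ci_seed=ci_seed)
    return CohortEvaluation(
        sample_ids=ids,
        scores=scores,
        calls=calls,
        labels=labels,
        metrics=dm,
        comparator_metrics=comp,
        subgroups=subgroups,
    )


def run_pipeline(
    cohort: Cohort,
    reference_sites: Sequence[CpGSite],
    *,
    r2_min: float = DEFAULT_R2_MIN,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    min_cov: float = DEFAULT_MIN_COV,
    max_cov: float = DEFAULT_MAX_COV,
    min_frac: float = DEFAULT_MIN_FRAC,
    alpha: float = DEFAULT_ALPHA,
    min_markers: int = 10,
    knn_k: int = DEFAULT_KNN_K,
    rfecv_folds: int = 10,
    rfecv_estimators: int = 100,
    grid: Mapping | None = None,
    threshold_reps: int = 3,
    threshold_folds: int = 5,
    seed: int = 0,
    evaluate: Sequence[str] = ("validation", "test"),
) -> PipelineResult:
    """Run the whole diagnostic pipeline on a cohort with all three splits.

    When fewer than ``min_markers`` blocks pass the screen (as happens under a
    null cohort), the ``min_markers`` lowest-p blocks are taken instead so a
    model can still be fit; a warning is logged. Fully reproducible given
    ``seed``.
    """
    disc = cohort.split("discovery")
    if not disc:
        raise ValueError("cohort has no discovery samples")
    disc_ids = [m.sample_id for m in disc]
    labels = pd.Series({m.sample_id: m.label for m in cohort.samples if m.label})

    pooled = [r for sid in disc_ids for r in cohort.haplotypes.get(sid, [])]
    index = SiteIndex(reference_sites)
    mhbs = call_mhbs(
        pooled, index.sites, r2_min=r2_min, min_cpgs=min_cpgs,
        min_pairs=min_pairs, max_gap_bp=max_gap_bp,
    )
    logger.info("called %d MHBs from %d pooled discovery reads", len(mhbs), len(pooled))
    if not mhbs:
        raise ValueError("no methylation haplotype blocks could be called")

    matrix = build_metric_matrix(cohort, mhbs, index)
    disc_matrix = matrix.subset_samples(disc_ids)

    retained = filter_blocks_by_coverage(disc_matrix, min_cov, max_cov, min_frac)
    logger.info("%d/%d blocks pass the coverage filter", len(retained), len(mhbs))
    retained_cols = disc_matrix.values.loc[:, retained]

    screen = screen_markers(retained_cols, labels, alpha=alpha)
    screened_cols = [(r.block_id, r.chosen_metric) for r in screen]
    if len(screened_cols) < min_markers:
        logger.warning(
            "only %d markers passed the p<%g screen; falling back to the %d lowest-p blocks",
            len(screened_cols), alpha, min_markers,
        )
        relaxed = screen_markers(retained_cols, labels, alpha=np.inf)
        relaxed.sort(key=lambda r: r.p_two_sided)
        screen = relaxed[:min_markers]
        screened_cols = [(r.block_id, r.chosen_metric) for r in screen]

    disc_features = retained_cols[screened_cols]
    completed, _ = impute_missing_knn(disc_features, k=knn_k)
    constant = completed.columns[completed.std(axis=0, ddof=0).to_numpy() == 0]
    if len(constant):
        logger.warning("dropping %d constant marker column(s)", len(constant))
        completed = completed.drop(columns=list(constant))
        keep = set(map(tuple, completed.columns))
        screen = [r for r in screen if (r.block_id, r.chosen_metric) in keep]
        disc_features = disc_features[list(completed.columns)]
    marker_set = rfecv_select(
        completed,
        labels.loc[disc_ids],
        folds=rfecv_folds,
        seed=seed,
        n_estimators=rfecv_estimators,
        screen_results=screen,
    )

    final_cols = marker_set.markers
    raw_final = disc_features[[tuple(c) for c in final_cols]]
    completed_final = completed[[tuple(c) for c in final_cols]]
    z, std_state = standardize(completed_final)
    forest = train_forest(z, labels.loc[disc_ids], grid=grid, seed=seed)

    threshold, fold_thresholds = derive_threshold(
        raw_final,
        labels.loc[disc_ids],
        reps=threshold_reps,
        folds=threshold_folds,
        seed=seed,
        knn_k=knn_k,
    )
    # the imputation reference applied to held-out samples is the raw
    # discovery marker matrix (pooled one-at-a-time at scoring time)
    _, impute_state = impute_missing_knn(raw_final, k=knn_k)
    bundle = ModelBundle(
        marker_set=marker_set,
        impute_state=impute_state,
        standardization=std_state,
        forest=forest,
        threshold=threshold,
        seed=seed,
        config_digest=config_digest(
            dict(r2_min=r2_min, min_cpgs=min_cpgs, alpha=alpha, knn_k=knn_k, seed=seed)
        ),
    )

    result = PipelineResult(
        mhbs=mhbs,
        metric_matrix=matrix,
        retained_blocks=retained,
        screen_results=screen,
        marker_set=marker_set,
        bundle=bundle,
        fold_thresholds=fold_thresholds,
    )
    for name in evaluate:
        if cohort.split(name):
            result.evaluations[name] = evaluate_cohort(bundle, matrix, cohort, name, ci_seed=seed)
    return result
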