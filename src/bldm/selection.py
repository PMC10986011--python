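"""Marker screening and selection.

The marker funnel mirrors standard practice for haplotype-level methylation
classifiers: (1) keep blocks with adequate coverage in most samples, (2) for
each block pick the single measurement (of the six) with the lowest two-sided
Mann-Whitney U p-value between the malignant and benign groups and keep blocks
passing a raw ``p < alpha`` screen, (3) complete missing values by KNN
imputation over samples, and (4) reduce to the final marker set by recursive
feature elimination with cross-validated random forests (RFECV).

Screening is done on observed values (pairwise deletion); imputation happens
afterwards on the screened matrix. No multiple-testing correction is applied
at the screen stage — the screen is a raw p-value gate by design.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.impute import KNNImputer
from sklearn.model_selection import StratifiedKFold

from bldm.metrics import METRIC_NAMES, MetricMatrix

logger = logging.getLogger(__name__)

# fixed precedence for breaking exact p-value ties between a block's metrics
METRIC_PRECEDENCE = ("amf", "mhl", "umhl", "mhl3", "umhl3", "pdr")

DEFAULT_MIN_COV = 10.0
DEFAULT_MAX_COV = 500.0
DEFAULT_MIN_FRAC = 0.8
DEFAULT_ALPHA = 0.001
DEFAULT_KNN_K = 5


def filter_blocks_by_coverage(
    matrix: MetricMatrix,
    min_cov: float = DEFAULT_MIN_COV,
    max_cov: float = DEFAULT_MAX_COV,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> list[str]:
    """Blocks with ``min_cov <= coverage < max_cov`` in at least ``min_frac`` of samples.

    The fraction comparison is inclusive (``>= min_frac``), so e.g. 8 of 10
    samples passes at ``min_frac = 0.8``.
    """
    cov = matrix.coverage
    if cov.shape[0] == 0:
        return []
    ok = (cov >= min_cov) & (cov < max_cov)
    frac = ok.mean(axis=0)
    return [b for b in cov.columns if frac[b] >= min_frac]


@dataclass(frozen=True, slots=True)
class MannWhitneyResult:
    u: float
    p: float
    defined: bool = True


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with exact small-sample handling.

    Missing values are dropped per group. The exact null distribution is used
    when both groups have at most 8 observations and there are no ties;
    otherwise the tie-corrected normal approximation (with continuity
    correction) applies. Completely tied data yield p = 1. A group with no
    observed values yields a flagged-undefined result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        return MannWhitneyResult(np.nan, np.nan, defined=False)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(len(x) * len(y) / 2.0, 1.0)
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(x) <= 8 and len(y) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    p = float(min(res.pvalue, 1.0))
    return MannWhitneyResult(float(res.statistic), p)


@dataclass(frozen=True, slots=True)
class ScreenResult:
    """Best measurement for one block under the Mann-Whitney screen."""

    block_id: str
    chosen_metric: str
    u_statistic: float
    p_two_sided: float
    direction: int  # sign of the MTN - BTN location shift


def screen_markers(
    matrix: MetricMatrix | pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    alpha: float = DEFAULT_ALPHA,
    metrics: Sequence[str] | None = None,
    positive_label: str = "MTN",
    negative_label: str = "BTN",
) -> list[ScreenResult]:
    """Per block, pick the lowest-p metric and keep blocks with ``p < alpha``.

    The comparison is strictly less-than. Ties on the minimum p-value are
    broken by the fixed precedence AMF, MHL, UMHL, MHL3, UMHL3, PDR. Blocks
    whose every metric is undefined (a group entirely missing) are skipped.
    ``metrics`` restricts the tested measurement types (default: all six).
    """
    values = matrix.values if isinstance(matrix, MetricMatrix) else matrix
    labels = pd.Series(labels)
    metrics = tuple(metrics) if metrics is not None else METRIC_PRECEDENCE
    for m in metrics:
        if m not in METRIC_NAMES:
            raise ValueError(f"unknown metric {m!r}")

    pos_ids = [s for s in values.index if labels.get(s) == positive_label]
    neg_ids = [s for s in values.index if labels.get(s) == negative_label]
    block_ids = list(dict.fromkeys(values.columns.get_level_values(0)))

    results: list[ScreenResult] = []
    for block in block_ids:
        best: ScreenResult | None = None
        for metric in METRIC_PRECEDENCE:
            if metric not in metrics or (block, metric) not in values.columns:
                continue
            col = values[(block, metric)]
            x = col.loc[pos_ids].to_numpy(dtype=float)
            y = col.loc[neg_ids].to_numpy(dtype=float)
            res = mann_whitney_u(x, y)
            if not res.defined:
                continue
            if best is None or res.p < best.p_two_sided:
                shift = np.nanmedian(x) - np.nanmedian(y)
                direction = int(np.sign(shift)) if not np.isnan(shift) else 0
                best = ScreenResult(block, metric, res.u, res.p, direction)
        if best is not None and best.p_two_sided < alpha:
            results.append(best)
    return results


@dataclass
class KNNImputeState:
    """Frozen imputation reference: the discovery rows (with their NaNs)."""

    reference: pd.DataFrame
    k: int = DEFAULT_KNN_K


def impute_missing_knn(
    matrix: pd.DataFrame,
    k: int = DEFAULT_KNN_K,
    reference: KNNImputeState | None = None,
) -> tuple[pd.DataFrame, KNNImputeState]:
    """KNN-impute missing cells (mean of the k nearest samples).

    Distances are masked (NaN-aware) Euclidean over co-observed columns. In
    fit mode (``reference is None``) the matrix itself is the reference and is
    imputed jointly. In apply mode each row is imputed *one at a time*: the row
    is pooled with all reference (discovery) rows, the imputer is run on the
    pooled matrix, and the completed row is taken — held-out samples never
    inform each other.
    """
    all_missing = [c for c in matrix.columns if matrix[c].isna().all()]
    if reference is None:
        if all_missing:
            raise ValueError(f"columns with no observed value: {all_missing}")
        imputer = KNNImputer(n_neighbors=k)
        completed = imputer.fit_transform(matrix.to_numpy(dtype=float))
        out = pd.DataFrame(completed, index=matrix.index, columns=matrix.columns)
        return out, KNNImputeState(reference=matrix.copy(), k=k)

    ref = reference.reference
    if list(ref.columns) != list(matrix.columns):
        matrix = matrix.reindex(columns=ref.columns)
    rows = []
    imputer = KNNImputer(n_neighbors=reference.k)
    ref_arr = ref.to_numpy(dtype=float)
    for _, row in matrix.iterrows():
        pooled = np.vstack([ref_arr, row.to_numpy(dtype=float)[None, :]])
        completed = imputer.fit_transform(pooled)
        rows.append(completed[-1])
    out = pd.DataFrame(np.array(rows), index=matrix.index, columns=matrix.columns)
    return out, reference


@dataclass
class MarkerSet:
    """The final ordered marker list plus selection provenance."""

    markers: list[tuple[str, str]]  # (block_id, metric)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate (block, metric) markers")

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(self.markers)

    def to_json(self, path: str | Path) -> None:
        payload = {"markers": [list(m) for m in self.markers], "provenance": self.provenance}
        Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            markers=[tuple(m) for m in payload["markers"]],
            provenance=payload.get("provenance", {}),
        )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def rfecv_select(
    matrix: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    folds: int = 10,
    step: int = 1,
    seed: int = 0,
    scoring: str = "roc_auc",
    n_estimators: int = 100,
    screen_results: Sequence[ScreenResult] | None = None,
    positive_label: str = "MTN",
) -> MarkerSet:
    """Recursive feature elimination with cross-validation over screened markers.

    ``matrix`` holds only the screened marker columns (complete, no missing
    values). Elimination is by random-forest feature importance; the retained
    size maximises the mean CV score, with ties resolved toward the smaller
    set. Fully reproducible given ``seed``; per-size CV scores are kept in the
    returned provenance.
    """
    labels = pd.Series(labels, index=matrix.index) if not isinstance(labels, pd.Series) else labels
    y = (labels.loc[matrix.index] == positive_label).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if matrix.isna().any().any():
        raise ValueError("RFECV input must be complete; impute first")

    estimator = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        class_weight="balanced",
        random_state=seed,
    )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    selector = RFECV(estimator, step=step, cv=cv, scoring=scoring, min_features_to_select=1)
    selector.fit(matrix.to_numpy(dtype=float), y)

    chosen = [matrix.columns[i] for i in range(matrix.shape[1]) if selector.support_[i]]
    markers = [tuple(c) for c in chosen]
    provenance = {
        "seed": seed,
        "folds": folds,
        "step": step,
        "scoring": scoring,
        "n_estimators": n_estimators,
        "cv_mean_scores": selector.cv_results_["mean_test_score"].tolist(),
        "n_features_candidates": selector.cv_results_.get("n_features", np.array([])).tolist(),
    }
    if screen_results is not None:
        provenance["screen_p_values"] = {
            f"{r.block_id}:{r.chosen_metric}": r.p_two_sided for r in screen_results
        }
    logger.info("RFECV retained %d of %d markers", len(markers), matrix.shape[1])
    return MarkerSet(markers=markers, provenance=provenance)
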