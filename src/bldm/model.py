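"""Random-forest diagnostic model, Youden-derived cutoff and evaluation battery.

The classifier scores a sample with the forest's probability of the malignant
class ("methylation score" in [0, 1]). The decision threshold is derived on
the discovery cohort by repeated stratified cross-validation: in every
held-out fold the Youden-optimal threshold (maximising J = sensitivity +
specificity - 1, with call rule score >= t -> malignant) is found, and the
mean over all folds is adopted as the model cutoff.

Evaluation covers the full diagnostic battery: confusion-count metrics
(sensitivity, specificity, PPV, NPV, accuracy, as percentages), the
rank-statistic AUC with a stratified-bootstrap percentile CI, an
ultrasonography comparator (ACR TI-RADS >= 4 counted as test-positive), and
subgroup strata (TI-RADS >= 4 / = 4 / = 5; micronodules <= 10 mm and
non-micronodules), plus the standard precision-based sample-size formula
n = ceil(z^2 P (1 - P) / d^2).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from bldm.io import SampleMeta
from bldm.selection import KNNImputeState, MarkerSet, impute_missing_knn

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "MTN"
NEGATIVE_LABEL = "BTN"

DEFAULT_FOREST_PARAMS = dict(
    n_estimators=500,
    max_features="sqrt",
    class_weight="balanced",
)
# small default grid; the winning point is refit on the full discovery set
DEFAULT_GRID = {"max_depth": [None, 10], "min_samples_leaf": [1, 3]}


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationState:
    """Per-marker location/scale fitted on discovery (population-SD convention)."""

    mean: pd.Series
    scale: pd.Series
    ddof: int = 0


def standardize(
    matrix: pd.DataFrame, fitted: StandardizationState | None = None
) -> tuple[pd.DataFrame, StandardizationState]:
    """Z-score features; fit mode uses the matrix's own mean/SD (ddof=0).

    Raises on zero-variance markers (fit mode) or on missing values.
    """
    if matrix.isna().any().any():
        raise ValueError("standardize expects a complete matrix; impute first")
    if fitted is None:
        mean = matrix.mean(axis=0)
        scale = matrix.std(axis=0, ddof=0)
        zero = [str(c) for c in matrix.columns[scale.to_numpy() == 0]]
        if zero:
            raise ValueError(f"zero-variance markers: {zero}")
        fitted = StandardizationState(mean=mean, scale=scale, ddof=0)
    z = (matrix - fitted.mean) / fitted.scale
    return z, fitted


# ---------------------------------------------------------------------------
# forest training and scoring
# ---------------------------------------------------------------------------

def train_forest(
    features: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    cv_folds: int = 10,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
    scoring: str = "roc_auc",
    forest_params: Mapping | None = None,
) -> RandomForestClassifier:
    """Grid-search forest hyperparameters by stratified CV, refit on all data.

    Ties between grid points resolve to the first point in declared grid
    order. Reproducible given ``seed``.
    """
    labels = pd.Series(labels, index=features.index) if not isinstance(labels, pd.Series) else labels
    y = (labels.loc[features.index] == POSITIVE_LABEL).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {cv_folds} folds"
        )
    params = dict(DEFAULT_FOREST_PARAMS)
    if forest_params:
        params.update(forest_params)
    base = RandomForestClassifier(random_state=seed, **params)
    search = GridSearchCV(
        base,
        param_grid=dict(grid) if grid is not None else DEFAULT_GRID,
        scoring=scoring,
        cv=StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed),
        refit=True,
    )
    search.fit(features.to_numpy(dtype=float), y)
    logger.info("selected forest hyperparameters: %s", search.best_params_)
    return search.best_estimator_


@dataclass
class ModelBundle:
    """Frozen fitted state of the diagnostic model.

    Scoring a sample applies, in order: KNN imputation against the pooled
    discovery reference, z-score standardization with discovery parameters,
    and the fitted forest's malignant-class probability. ``threshold`` is the
    Youden-derived cutoff; calls use score >= threshold -> malignant.
    """

    marker_set: MarkerSet
    impute_state: KNNImputeState
    standardization: StandardizationState
    forest: RandomForestClassifier
    threshold: float
    seed: int = 0
    config_digest: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0,1), got {self.threshold}")
        if (self.standardization.scale.to_numpy() <= 0).any():
            raise ValueError("standardization scale must be positive for every marker")

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, cls):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


def config_digest(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(dict(config), sort_keys=True, default=str).encode()).hexdigest()[:16]


def score(bundle: ModelBundle, features: pd.DataFrame) -> np.ndarray:
    """Methylation scores in [0, 1] for rows of ``features`` (marker columns).

    Missing marker columns raise; missing values are imputed one sample at a
    time against the discovery reference. An all-missing sample is imputed
    from the reference alone (with a warning) rather than refused.
    """
    wanted = [tuple(m) for m in bundle.marker_set.markers]
    missing_cols = [m for m in wanted if m not in set(map(tuple, features.columns))]
    if missing_cols:
        raise ValueError(f"features lack marker columns: {missing_cols}")
    sub = features[wanted]
    all_missing = sub.index[sub.isna().all(axis=1)]
    for sid in all_missing:
        logger.warning("sample %s has no observed marker values; imputing all from reference", sid)
    completed, _ = impute_missing_knn(sub, reference=bundle.impute_state)
    z, _ = standardize(completed, fitted=bundle.standardization)
    return bundle.forest.predict_proba(z.to_numpy(dtype=float))[:, 1]


# ---------------------------------------------------------------------------
# threshold derivation
# ---------------------------------------------------------------------------

def youden_optimal_threshold(scores: Sequence[float], labels: Sequence) -> float:
    """Threshold maximising J = sensitivity + specificity - 1 (rule: >= t positive).

    Candidates are midpoints of adjacent distinct scores plus the boundary
    candidates (everything positive / everything negative); exact ties on J
    resolve to the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if y.all() or not y.any():
        raise ValueError("both classes are required to derive a threshold")
    distinct = np.unique(scores)
    candidates = [float(distinct[0])]
    candidates += [float((a + b) / 2) for a, b in zip(distinct[:-1], distinct[1:])]
    candidates.append(float(np.nextafter(distinct[-1], np.inf)))
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    best_t = candidates[0]
    best_j = None
    for t in candidates:
        calls = scores >= t
        # exact tie handling: J ranking via the integer tp*n_neg + tn*n_pos
        j = int((calls & y).sum()) * n_neg + int((~calls & ~y).sum()) * n_pos
        if best_j is None or j > best_j:  # strict: smaller candidates win ties
            best_j = j
            best_t = t
    return float(best_t)


def derive_threshold(
    features: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    reps: int = 3,
    folds: int = 5,
    seed: int = 0,
    knn_k: int = 5,
    forest_params: Mapping | None = None,
    n_estimators: int = 500,
) -> tuple[float, list[float]]:
    """Mean held-out Youden-optimal threshold over ``reps`` x ``folds`` CV.

    For each fold the full pipeline (imputation, standardization, forest) is
    refit on the training portion and the Youden-optimal threshold is found on
    the held-out scores. Returns (mean threshold, all fold thresholds).
    ``features`` may contain missing values; labels must cover its rows.
    """
    labels = pd.Series(labels, index=features.index) if not isinstance(labels, pd.Series) else labels
    y = (labels.loc[features.index] == POSITIVE_LABEL).to_numpy()
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < folds:
        raise ValueError(f"each class needs >= {folds} samples for {folds}-fold CV")
    params = dict(DEFAULT_FOREST_PARAMS)
    params["n_estimators"] = n_estimators
    if forest_params:
        params.update(forest_params)

    thresholds: list[float] = []
    X = features
    for rep in range(reps):
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in cv.split(np.zeros(len(y)), y):
            X_tr = X.iloc[train_idx]
            X_te = X.iloc[test_idx]
            completed_tr, imp_state = impute_missing_knn(X_tr, k=knn_k)
            z_tr, std_state = standardize(completed_tr)
            forest = RandomForestClassifier(random_state=seed + rep, **params)
            forest.fit(z_tr.to_numpy(dtype=float), y[train_idx])
            completed_te, _ = impute_missing_knn(X_te, reference=imp_state)
            z_te, _ = standardize(completed_te, fitted=std_state)
            s = forest.predict_proba(z_te.to_numpy(dtype=float))[:, 1]
            thresholds.append(youden_optimal_threshold(s, y[test_idx]))
    return float(np.mean(thresholds)), thresholds


# ---------------------------------------------------------------------------
# diagnostic metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(slots=True)
class DiagnosticMetrics:
    """Percent-scale diagnostic metrics; undefined ratios are ``None``, never 0."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    counts: ConfusionCounts | None = None

    def rounded(self, ndigits: int = 2) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, ndigits)
        out["auc"] = None if self.auc is None else round(self.auc, 3)
        return out


def _ratio_pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def confusion_metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV/accuracy (percent) from confusion counts.

    All values are computed at full precision; rounding to two decimals is a
    presentation concern (:meth:`DiagnosticMetrics.rounded`).
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    return DiagnosticMetrics(
        sensitivity=_ratio_pct(counts.tp, counts.tp + counts.fn),
        specificity=_ratio_pct(counts.tn, counts.tn + counts.fp),
        ppv=_ratio_pct(counts.tp, counts.tp + counts.fp),
        npv=_ratio_pct(counts.tn, counts.tn + counts.fn),
        accuracy=_ratio_pct(counts.tp + counts.tn, counts.total),
        counts=counts,
    )


def confusion_from_calls(calls: Sequence[bool], labels: Sequence) -> ConfusionCounts:
    calls = np.asarray(calls, dtype=bool)
    y = _as_bool_labels(labels)
    return ConfusionCounts(
        tp=int((calls & y).sum()),
        fp=int((calls & ~y).sum()),
        tn=int((~calls & ~y).sum()),
        fn=int((~calls & y).sum()),
    )


def _as_bool_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return np.array([v == POSITIVE_LABEL or v is True or v == 1 for v in arr], dtype=bool)


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """AUC via the rank-statistic (Mann-Whitney) formulation, ties counted 1/2.

    Identical to the trapezoidal ROC area.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes are required for AUC")
    ranks = stats.rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auc_ci(
    scores: Sequence[float],
    labels: Sequence,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUC (classes resampled separately)."""
    scores = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    pos = scores[y]
    neg = scores[~y]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    y_boot = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
    for i in range(n_boot):
        s = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        aucs[i] = roc_auc(s, y_boot)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(aucs, [alpha, 1 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# comparator, subgroups, sample size
# ---------------------------------------------------------------------------

def ultrasound_comparator(
    meta: Sequence[SampleMeta], tirads_cutoff: int = 4
) -> dict[str, bool]:
    """Binary ultrasonography calls: positive iff ACR TI-RADS >= ``tirads_cutoff``.

    Samples with missing TI-RADS are excluded (with a warning).
    """
    calls: dict[str, bool] = {}
    for s in meta:
        if s.tirads is None:
            logger.warning("sample %s has no TI-RADS category; excluded from comparator", s.sample_id)
            continue
        calls[s.sample_id] = s.tirads >= tirads_cutoff
    return calls


STRATA = ("tirads_ge4", "tirads_4", "tirads_5", "micronodule", "non_micronodule")
MICRONODULE_MAX_MM = 10.0  # inclusive boundary: <= 10 mm is a micronodule


def _stratum_mask(meta: Sequence[SampleMeta], stratum: str) -> list[str]:
    out = []
    for s in meta:
        if stratum == "tirads_ge4":
            keep = s.tirads is not None and s.tirads >= 4
        elif stratum == "tirads_4":
            keep = s.tirads == 4
        elif stratum == "tirads_5":
            keep = s.tirads == 5
        elif stratum == "micronodule":
            keep = s.size_mm is not None and s.size_mm <= MICRONODULE_MAX_MM
        elif stratum == "non_micronodule":
            keep = s.size_mm is not None and s.size_mm > MICRONODULE_MAX_MM
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
        if keep:
            out.append(s.sample_id)
    return out


def subgroup_report(
    scores: Mapping[str, float],
    calls: Mapping[str, bool],
    meta: Sequence[SampleMeta],
    strata: Sequence[str] = STRATA,
    ci_seed: int = 0,
    n_boot: int = 2000,
) -> dict[str, DiagnosticMetrics | None]:
    """Per-stratum diagnostic metrics (plus AUC where both classes occur).

    Empty strata are reported as ``None`` rather than raising. Labels come
    from the sample metadata; samples without a label are skipped.
    """
    by_id = {s.sample_id: s for s in meta}
    report: dict[str, DiagnosticMetrics | None] = {}
    for stratum in strata:
        ids = [i for i in _stratum_mask(meta, stratum) if i in scores and by_id[i].label is not None]
        if not ids:
            report[stratum] = None
            continue
        y = [by_id[i].label for i in ids]
        cc = confusion_from_calls([calls[i] for i in ids], y)
        dm = confusion_metrics(cc)
        y_bool = _as_bool_labels(y)
        if y_bool.any() and not y_bool.all():
            s = [scores[i] for i in ids]
            dm.auc = roc_auc(s, y_bool)
            dm.auc_ci = auc_ci(s, y_bool, n_boot=n_boot, seed=ci_seed)
        report[stratum] = dm
    return report


def minimum_sample_size(P: float, d: float, conf: float = 0.95) -> int:
    """Per-group n to estimate a proportion P within +/- d at confidence ``conf``.

    ``n = ceil(z^2 P (1 - P) / d^2)`` with ``z`` the standard-normal quantile
    at ``1 - (1 - conf)/2``. Boundary values P in {0, 1} give n = 0.
    """
    if not 0 <= P <= 1:
        raise ValueError(f"P must be in [0, 1], got {P}")
    if d <= 0:
        raise ValueError(f"d must be > 0, got {d}")
    if not 0 < conf < 1:
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    return int(math.ceil(z * z * P * (1 - P) / (d * d)))
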