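"""Classifier, Youden cutoff, diagnostic metrics, AUC, comparator, sample size."""

import numpy as np
import pandas as pd
import pytest
from helpers import brute_auc, brute_youden
from hypothesis import given, strategies as st

from bldm.io import SampleMeta
from bldm.model import (
    ConfusionCounts,
    ModelBundle,
    auc_ci,
    confusion_from_calls,
    confusion_metrics,
    derive_threshold,
    minimum_sample_size,
    roc_auc,
    score,
    standardize,
    subgroup_report,
    train_forest,
    ultrasound_comparator,
    youden_optimal_threshold,
)
from bldm.selection import KNNImputeState, MarkerSet, impute_missing_knn


class TestStandardize:
    def test_population_sd_convention(self):
        df = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        z, state = standardize(df)
        assert np.allclose(z["m"], [-1.224744871, 0.0, 1.224744871])
        assert state.ddof == 0

    def test_apply_mode_reproduces_fit_mode(self, rng):
        df = pd.DataFrame(rng.random((8, 3)))
        z1, state = standardize(df)
        z2, _ = standardize(df, fitted=state)
        assert np.allclose(z1.to_numpy(), z2.to_numpy())

    def test_constant_column_errors(self):
        df = pd.DataFrame({"m": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="m"):
            standardize(df)


class TestForest:
    def test_separable_data_perfect_training_auc(self, rng):
        X = pd.DataFrame({"a": np.r_[rng.uniform(0, 0.3, 30), rng.uniform(0.7, 1, 30)],
                          "b": rng.random(60)})
        labels = pd.Series(["BTN"] * 30 + ["MTN"] * 30, index=X.index)
        f = train_forest(X, labels, cv_folds=5, seed=0)
        s = f.predict_proba(X.to_numpy())[:, 1]
        assert roc_auc(s, labels == "MTN") == pytest.approx(1.0)

    def test_same_seed_identical_scores(self, rng):
        X = pd.DataFrame(rng.random((40, 4)))
        labels = pd.Series(["BTN"] * 20 + ["MTN"] * 20, index=X.index)
        s1 = train_forest(X, labels, cv_folds=4, seed=9).predict_proba(X.to_numpy())[:, 1]
        s2 = train_forest(X, labels, cv_folds=4, seed=9).predict_proba(X.to_numpy())[:, 1]
        assert np.array_equal(s1, s2)

    def test_too_few_per_class_errors(self, rng):
        X = pd.DataFrame(rng.random((6, 2)))
        labels = pd.Series(["MTN"] * 2 + ["BTN"] * 4, index=X.index)
        with pytest.raises(ValueError, match="folds"):
            train_forest(X, labels, cv_folds=3)


class TestYouden:
    def test_separated_clusters_midpoint(self):
        t = youden_optimal_threshold([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        assert t == pytest.approx(0.5)

    def test_identical_distributions_j_zero(self):
        scores = [0.3, 0.7, 0.3, 0.7]
        y = [True, True, False, False]
        t = youden_optimal_threshold(scores, y)
        calls = np.asarray(scores) >= t
        yb = np.asarray(y)
        j = calls[yb].mean() + (~calls[~yb]).mean() - 1
        assert j == pytest.approx(0.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            youden_optimal_threshold([0.1, 0.9], [True, True])

    def test_exhaustive_oracle_agreement(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            t = youden_optimal_threshold(scores, y)
            j_best, t_best = brute_youden(scores, y)
            assert t == pytest.approx(t_best)

    def test_invariance_under_monotone_transform(self, rng):
        scores = rng.random(30)
        y = rng.random(30) < 0.4
        if y.all() or not y.any():
            y[0] = True
            y[1] = False
        t = youden_optimal_threshold(scores, y)
        calls = scores >= t
        f = lambda s: 1 / (1 + np.exp(-5 * (s - 0.5)))  # strictly increasing
        t2 = youden_optimal_threshold(f(scores), y)
        assert np.array_equal(f(scores) >= t2, calls)


class TestDeriveThreshold:
    def test_separable_cohort_threshold_between_clusters(self, rng):
        n = 20
        X = pd.DataFrame(
            {"m1": np.r_[rng.uniform(0, 0.2, n), rng.uniform(0.8, 1, n)],
             "m2": np.r_[rng.uniform(0, 0.2, n), rng.uniform(0.8, 1, n)]}
        )
        labels = pd.Series(["BTN"] * n + ["MTN"] * n, index=X.index)
        t, folds = derive_threshold(X, labels, reps=2, folds=4, seed=0, n_estimators=50)
        assert 0.0 < t < 1.0
        assert len(folds) == 8
        # every fold's threshold separates the held-out clusters on separable data
        assert all(0.05 < ft < 0.95 for ft in folds)

    def test_degenerate_folding_rejected(self, rng):
        X = pd.DataFrame({"m": rng.random(8)})
        labels = pd.Series(["MTN"] * 2 + ["BTN"] * 6, index=X.index)
        with pytest.raises(ValueError, match="fold"):
            derive_threshold(X, labels, folds=5)


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            # validation-cohort printed counts: 35/42 malignant, 50/55 benign correct
            (
                ConfusionCounts(tp=35, fn=7, tn=50, fp=5),
                dict(sensitivity=83.33, specificity=90.91, ppv=87.50, npv=87.72, accuracy=87.63),
            ),
            # independent-test printed counts: 29/35 and 47/53
            (
                ConfusionCounts(tp=29, fn=6, tn=47, fp=6),
                dict(sensitivity=82.86, specificity=88.68, ppv=82.86, npv=88.68, accuracy=86.36),
            ),
        ],
    )
    def test_printed_contingency_tables(self, counts, expected):
        got = confusion_metrics(counts).rounded()
        for k, v in expected.items():
            assert got[k] == pytest.approx(v, abs=1e-9)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fp=0, tn=0, fn=0))
        assert m.sensitivity == 100.0 and m.ppv == 100.0 and m.accuracy == 100.0
        assert m.specificity is None  # no negatives: undefined, not 0

    def test_empty_denominators_flagged(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m.ppv is None and m.specificity == 100.0

    @given(
        st.tuples(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
    )
    def test_identities_hold_for_all_counts(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
        if tp + fn:
            assert m.sensitivity == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert m.specificity == pytest.approx(100 * tn / (tn + fp))
        assert m.accuracy == pytest.approx(100 * (tp + tn) / (tp + fp + tn + fn))


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.random(2000)
        y = rng.random(2000) < 0.5
        assert roc_auc(scores, y) == pytest.approx(0.5, abs=0.05)

    def test_pairwise_brute_force_agreement(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.random(n), 1)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            assert roc_auc(scores, y) == pytest.approx(brute_auc(scores, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(50)
        y = rng.random(50) < 0.5
        y[0], y[1] = True, False
        assert roc_auc(np.exp(3 * scores), y) == pytest.approx(roc_auc(scores, y))

    def test_bootstrap_ci_brackets_auc(self, rng):
        scores = np.r_[rng.normal(1, 1, 50), rng.normal(0, 1, 50)]
        y = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        lo, hi = auc_ci(scores, y, n_boot=500, seed=1)
        a = roc_auc(scores, y)
        assert lo <= a <= hi and hi - lo < 0.35


class TestComparatorAndSubgroups:
    METAS = [
        SampleMeta("P1", "MTN", "validation", tirads=5, size_mm=8.0),
        SampleMeta("P2", "BTN", "validation", tirads=4, size_mm=15.0),
        SampleMeta("P3", "BTN", "validation", tirads=3, size_mm=10.0),
        SampleMeta("P4", "MTN", "validation", tirads=None, size_mm=9.0),
    ]

    def test_tirads_binarization(self):
        calls = ultrasound_comparator(self.METAS)
        assert calls == {"P1": True, "P2": True, "P3": False}  # P4: missing tirads

    def test_micronodule_partition(self):
        scores = {m.sample_id: 0.5 for m in self.METAS}
        calls = {m.sample_id: True for m in self.METAS}
        rep = subgroup_report(scores, calls, self.METAS, strata=("micronodule", "non_micronodule"), n_boot=10)
        micro = rep["micronodule"].counts
        non = rep["non_micronodule"].counts
        # size boundary is inclusive: 10 mm counts as micronodule
        assert micro.total == 3 and non.total == 1
        assert micro.total + non.total == len(self.METAS)

    def test_stratum_without_positives_flags_sensitivity(self):
        metas = [SampleMeta("Q1", "BTN", "validation", tirads=4, size_mm=5.0)]
        rep = subgroup_report({"Q1": 0.2}, {"Q1": False}, metas, strata=("tirads_4",), n_boot=10)
        assert rep["tirads_4"].sensitivity is None
        assert rep["tirads_4"].specificity == 100.0

    def test_empty_stratum_reported_none(self):
        rep = subgroup_report({}, {}, [], strata=("tirads_5",), n_boot=10)
        assert rep["tirads_5"] is None


class TestSampleSize:
    def test_target_precision_for_ninety_percent(self):
        assert minimum_sample_size(P=0.90, d=0.1, conf=0.95) == 35

    def test_half_width_half(self):
        assert minimum_sample_size(P=0.5, d=0.5, conf=0.95) == 4

    def test_boundary_p(self):
        assert minimum_sample_size(P=1.0, d=0.1) == 0
        assert minimum_sample_size(P=0.0, d=0.1) == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            minimum_sample_size(P=0.9, d=0.0)
        with pytest.raises(ValueError):
            minimum_sample_size(P=1.2, d=0.1)


class TestBundle:
    def _tiny_bundle(self, rng):
        ref = pd.DataFrame(
            rng.random((20, 2)), columns=pd.MultiIndex.from_tuples([("B1", "amf"), ("B2", "mhl")])
        )
        labels = pd.Series(["MTN"] * 10 + ["BTN"] * 10, index=ref.index)
        ref.iloc[:10] += 0.5
        completed, imp = impute_missing_knn(ref, k=3)
        z, std = standardize(completed)
        forest = train_forest(z, labels, cv_folds=3, seed=2, grid={"max_depth": [None]})
        return ModelBundle(
            marker_set=MarkerSet([("B1", "amf"), ("B2", "mhl")]),
            impute_state=imp,
            standardization=std,
            forest=forest,
            threshold=0.5,
            seed=2,
        ), ref

    def test_save_load_identical_scores(self, tmp_path, rng):
        bundle, ref = self._tiny_bundle(rng)
        s1 = score(bundle, ref)
        p = tmp_path / "model.joblib"
        bundle.save(p)
        s2 = score(ModelBundle.load(p), ref)
        assert np.array_equal(s1, s2)

    def test_scoring_deterministic(self, rng):
        bundle, ref = self._tiny_bundle(rng)
        assert np.array_equal(score(bundle, ref), score(bundle, ref))

    def test_missing_marker_column_errors(self, rng):
        bundle, ref = self._tiny_bundle(rng)
        with pytest.raises(ValueError, match="B2"):
            score(bundle, ref[[("B1", "amf")]])

    def test_all_missing_sample_scored_with_warning(self, rng, caplog):
        bundle, ref = self._tiny_bundle(rng)
        row = pd.DataFrame(
            [[np.nan, np.nan]], columns=ref.columns, index=["empty"]
        )
        with caplog.at_level("WARNING"):
            s = score(bundle, row)
        assert 0.0 <= s[0] <= 1.0
        assert "empty" in caplog.text

    def test_threshold_bounds_enforced(self, rng):
        bundle, _ = self._tiny_bundle(rng)
        with pytest.raises(ValueError, match="threshold"):
            ModelBundle(
                marker_set=bundle.marker_set,
                impute_state=bundle.impute_state,
                standardization=bundle.standardization,
                forest=bundle.forest,
                threshold=1.5,
            )
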