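"""Marker funnel: coverage filter, Mann-Whitney screen, KNN imputation, RFECV."""

import numpy as np
import pandas as pd
import pytest
from helpers import exact_mwu_two_sided_p

from bldm.metrics import METRIC_NAMES, MetricMatrix
from bldm.selection import (
    filter_blocks_by_coverage,
    impute_missing_knn,
    mann_whitney_u,
    rfecv_select,
    screen_markers,
)


def _matrix_from_cov(cov: np.ndarray) -> MetricMatrix:
    n, b = cov.shape
    blocks = [f"B{i}" for i in range(b)]
    cols = pd.MultiIndex.from_tuples([(bl, m) for bl in blocks for m in METRIC_NAMES])
    values = pd.DataFrame(0.5, index=[f"S{i}" for i in range(n)], columns=cols)
    coverage = pd.DataFrame(cov, index=values.index, columns=blocks)
    return MetricMatrix(values, coverage)


class TestCoverageFilter:
    def test_boundary_fraction_inclusive(self):
        cov = np.full((10, 1), 12.0)
        cov[:2, 0] = 5.0  # 8/10 pass -> exactly min_frac
        assert filter_blocks_by_coverage(_matrix_from_cov(cov)) == ["B0"]

    def test_high_coverage_excluded(self):
        cov = np.full((10, 1), 12.0)
        cov[:3, 0] = 600.0  # 7/10 in range < 0.8
        assert filter_blocks_by_coverage(_matrix_from_cov(cov)) == []

    def test_min_frac_zero_keeps_all(self):
        cov = np.zeros((5, 3))
        m = _matrix_from_cov(cov)
        assert filter_blocks_by_coverage(m, min_frac=0.0) == ["B0", "B1", "B2"]

    def test_tightening_bounds_never_adds_blocks(self, rng):
        cov = rng.gamma(2.0, 15.0, size=(30, 20))
        m = _matrix_from_cov(cov)
        loose = set(filter_blocks_by_coverage(m, min_cov=5, max_cov=1000, min_frac=0.7))
        tight = set(filter_blocks_by_coverage(m, min_cov=10, max_cov=500, min_frac=0.8))
        assert tight <= loose

    def test_empty_matrix(self):
        assert filter_blocks_by_coverage(_matrix_from_cov(np.empty((0, 2)))) == []


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.1)
        assert res.p == pytest.approx(exact_mwu_two_sided_p([1, 2, 3], [4, 5, 6]))

    def test_two_sided_symmetry(self):
        a, b = [1.2, 3.4, 0.5, 8], [2.2, 5.1, 9.9]
        assert mann_whitney_u(a, b).p == pytest.approx(mann_whitney_u(b, a).p)

    def test_complete_ties_p_one(self):
        assert mann_whitney_u([5, 5, 5], [5, 5, 5]).p == 1.0

    def test_missing_values_dropped(self):
        res = mann_whitney_u([1, 2, 3, np.nan], [4, 5, np.nan, 6])
        assert res.p == pytest.approx(0.1)

    def test_empty_group_flagged_undefined(self):
        assert not mann_whitney_u([np.nan, np.nan], [1, 2, 3]).defined

    def test_exact_matches_enumeration_on_random_sets(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            vals = rng.permutation(np.arange(1, n1 + n2 + 1)).astype(float)
            x, y = vals[:n1], vals[n1:]
            assert mann_whitney_u(x, y).p == pytest.approx(
                exact_mwu_two_sided_p(x, y), abs=1e-12
            )


def _screen_matrix(rng, n_blocks, n_per_group, delta_blocks=(), delta=0.0):
    """Beta-distributed metric columns; all six metrics share the block signal."""
    samples = [f"M{i}" for i in range(n_per_group)] + [f"B{i}" for i in range(n_per_group)]
    labels = pd.Series(["MTN"] * n_per_group + ["BTN"] * n_per_group, index=samples)
    cols = {}
    for b in range(n_blocks):
        base = 0.4
        shift = delta if b in delta_blocks else 0.0
        mtn = rng.beta((base + shift) * 30, (1 - base - shift) * 30, size=n_per_group)
        btn = rng.beta(base * 30, (1 - base) * 30, size=n_per_group)
        col = np.concatenate([mtn, btn])
        for m in METRIC_NAMES:
            noise = rng.normal(0, 0.02, size=len(col))
            cols[(f"B{b}", m)] = np.clip(col + noise, 0, 1)
    values = pd.DataFrame(cols, index=samples)
    values.columns = pd.MultiIndex.from_tuples(values.columns)
    return values, labels


class TestScreen:
    def test_planted_blocks_recovered(self, rng):
        values, labels = _screen_matrix(rng, 20, 40, delta_blocks=set(range(5)), delta=0.25)
        results = screen_markers(values, labels, alpha=0.001)
        hit = {r.block_id for r in results}
        assert {f"B{i}" for i in range(5)} <= hit
        for r in results:
            if r.block_id in {f"B{i}" for i in range(5)}:
                assert r.direction == 1  # planted shift raises MTN methylation

    def test_chosen_metric_has_min_p(self, rng):
        values, labels = _screen_matrix(rng, 5, 20, delta_blocks={0}, delta=0.2)
        results = screen_markers(values, labels, alpha=1.0)
        for r in results:
            ps = []
            for m in METRIC_NAMES:
                x = values[(r.block_id, m)].loc[labels == "MTN"]
                y = values[(r.block_id, m)].loc[labels == "BTN"]
                ps.append(mann_whitney_u(x, y).p)
            assert r.p_two_sided == pytest.approx(min(ps))

    def test_alpha_monotone(self, rng):
        values, labels = _screen_matrix(rng, 15, 25, delta_blocks={0, 1}, delta=0.15)
        loose = {r.block_id for r in screen_markers(values, labels, alpha=0.05)}
        tight = {r.block_id for r in screen_markers(values, labels, alpha=0.001)}
        assert tight <= loose

    def test_screen_deterministic(self, rng):
        values, labels = _screen_matrix(rng, 10, 15, delta_blocks={2}, delta=0.2)
        a = screen_markers(values, labels, alpha=0.5)
        b = screen_markers(values, labels, alpha=0.5)
        assert a == b

    def test_null_calibration_single_metric(self, rng):
        """Pass fraction under exchangeable labels matches alpha (99% binomial bounds)."""
        from scipy.stats import binom

        n_blocks, n = 2000, 40
        samples = [f"S{i}" for i in range(2 * n)]
        labels = pd.Series(["MTN"] * n + ["BTN"] * n, index=samples)
        cols = {
            (f"B{b}", "amf"): rng.beta(8, 12, size=2 * n) for b in range(n_blocks)
        }
        values = pd.DataFrame(cols, index=samples)
        values.columns = pd.MultiIndex.from_tuples(values.columns)
        alpha = 0.01
        results = screen_markers(values, labels, alpha=alpha, metrics=["amf"])
        lo = binom.ppf(0.005, n_blocks, alpha)
        hi = binom.ppf(0.995, n_blocks, alpha)
        assert lo <= len(results) <= hi


class TestImpute:
    def test_complete_matrix_unchanged(self, rng):
        df = pd.DataFrame(rng.random((6, 4)))
        out, state = impute_missing_knn(df, k=2)
        assert np.allclose(out.to_numpy(), df.to_numpy())

    def test_k1_duplicate_row_forcing(self):
        df = pd.DataFrame(
            [[0.2, 0.4, 0.6], [0.2, 0.4, 0.6], [0.9, 0.9, 0.9], [0.2, np.nan, 0.6]],
            index=list("abcd"),
        )
        out, _ = impute_missing_knn(df, k=1)
        assert out.loc["d", 1] == pytest.approx(0.4)

    def test_all_missing_column_errors(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="y"):
            impute_missing_knn(df)

    def test_masking_beats_column_mean(self, rng):
        # correlated columns -> KNN should beat column-mean imputation
        latent = rng.random((40, 1))
        full = np.clip(latent + rng.normal(0, 0.05, size=(40, 8)), 0, 1)
        df = pd.DataFrame(full)
        mask = rng.random(full.shape) < 0.1
        mask[:, 0] = False  # keep one anchored column
        masked = df.mask(mask)
        out, _ = impute_missing_knn(masked, k=5)
        knn_rmse = np.sqrt(np.nanmean((out.to_numpy() - full)[mask.nonzero()] ** 2))
        col_mean = masked.fillna(masked.mean())
        mean_rmse = np.sqrt(np.nanmean((col_mean.to_numpy() - full)[mask.nonzero()] ** 2))
        assert knn_rmse < mean_rmse

    def test_apply_mode_one_at_a_time(self, rng):
        ref_df = pd.DataFrame(rng.random((10, 3)))
        _, state = impute_missing_knn(ref_df, k=3)
        held = pd.DataFrame([[np.nan, 0.5, 0.5], [0.1, np.nan, 0.1]], index=["h1", "h2"])
        out, _ = impute_missing_knn(held, reference=state)
        # each row imputed against the reference only: single-row calls agree
        for sid in held.index:
            single, _ = impute_missing_knn(held.loc[[sid]], reference=state)
            assert np.allclose(single.to_numpy(), out.loc[[sid]].to_numpy())


class TestRfecv:
    def test_planted_informative_features_selected(self, rng):
        n = 60
        informative = np.vstack(
            [rng.normal(0.5, 1, (n, 2)), rng.normal(-0.5, 1, (n, 2))]
        )
        noise = rng.normal(0, 1, (2 * n, 18))
        X = pd.DataFrame(
            np.hstack([informative, noise]),
            columns=pd.MultiIndex.from_tuples(
                [("inf0", "amf"), ("inf1", "mhl")] + [(f"n{i}", "amf") for i in range(18)]
            ),
        )
        labels = pd.Series(["MTN"] * n + ["BTN"] * n, index=X.index)
        ms = rfecv_select(X, labels, folds=5, seed=3, n_estimators=60)
        chosen = set(ms.markers)
        assert ("inf0", "amf") in chosen and ("inf1", "mhl") in chosen

    def test_reproducible_given_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        X.columns = pd.MultiIndex.from_tuples([(f"b{i}", "amf") for i in range(6)])
        X.iloc[:20, 0] += 1.5
        labels = pd.Series(["MTN"] * 20 + ["BTN"] * 20, index=X.index)
        a = rfecv_select(X, labels, folds=4, seed=11, n_estimators=40)
        b = rfecv_select(X, labels, folds=4, seed=11, n_estimators=40)
        assert a.markers == b.markers

    def test_single_class_errors(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        X.columns = pd.MultiIndex.from_tuples([(f"b{i}", "amf") for i in range(3)])
        with pytest.raises(ValueError, match="single class"):
            rfecv_select(X, pd.Series(["MTN"] * 10, index=X.index), folds=2)

    def test_shuffled_labels_cv_auc_near_half(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 5)))
        X.columns = pd.MultiIndex.from_tuples([(f"b{i}", "amf") for i in range(5)])
        labels = pd.Series(rng.permutation(["MTN"] * 40 + ["BTN"] * 40), index=X.index)
        ms = rfecv_select(X, labels, folds=5, seed=5, n_estimators=40)
        best = max(ms.provenance["cv_mean_scores"])
        assert 0.3 <= best <= 0.7

    def test_marker_set_json_round_trip(self, tmp_path, rng):
        from bldm.selection import MarkerSet

        ms = MarkerSet([("B1", "amf"), ("B2", "pdr")], provenance={"seed": 1})
        p = tmp_path / "m.json"
        ms.to_json(p)
        back = MarkerSet.from_json(p)
        assert back.markers == ms.markers and back.provenance["seed"] == 1
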