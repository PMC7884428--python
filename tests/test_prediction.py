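"""Weighted Youden index, threshold scan, ROC/AUC, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from fddos.prediction import (
    bin_medians,
    kfold_cv,
    optimal_threshold,
    roc_and_auc,
    summarize_cv,
    threshold_scan,
    time_resolved_performance,
    weighted_youden,
)


class TestWeightedYouden:
    @pytest.mark.parametrize(
        "sens,spec,w,expected",
        [
            (0.0, 1.0, 0.1, 0.8),   # degenerate all-negative rule
            (1.0, 1.0, 0.1, 1.0),   # perfect prediction
            (1.0, 1.0, 0.7, 1.0),   # ceiling holds for any w
            (0.8, 1.0, 0.1, 0.96),
            (0.5, 0.5, 0.5, 0.0),   # chance performance
            (1.0, 0.0, 0.1, -0.8),
        ],
    )
    def test_reference_values(self, sens, spec, w, expected):
        assert weighted_youden(sens, spec, w) == pytest.approx(expected, abs=1e-12)

    @given(
        sens=st.floats(0, 1),
        spec=st.floats(0, 1),
        w=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_classical_reduction(self, sens, spec, w):
        j = weighted_youden(sens, spec, w)
        assert -1.0 - 1e-12 <= j <= 1.0 + 1e-12
        assert weighted_youden(sens, spec, 0.5) == pytest.approx(
            sens + spec - 1.0, abs=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            weighted_youden(1.2, 0.5, 0.1)
        with pytest.raises(ValueError):
            weighted_youden(0.5, 0.5, 1.5)


class TestThresholdScan:
    def test_scan_monotonicity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 40)
        y = rng.random(40) < 0.6
        scan = threshold_scan(v, y, 0.1)
        assert np.all(np.diff(scan.sensitivity) <= 1e-12)
        assert np.all(np.diff(scan.specificity) >= -1e-12)

    def test_separable_groups(self):
        res = optimal_threshold([5.0, 6.0, 7.0, 1.0, 2.0, 3.0],
                                [1, 1, 1, 0, 0, 0], 0.1)
        assert res.threshold == 5.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.j_w == pytest.approx(1.0)

    def test_constant_values_fall_back_to_all_negative_rule(self):
        res = optimal_threshold([3.0] * 6, [1, 1, 1, 1, 0, 0], 0.1)
        assert res.j_w == pytest.approx(0.8)
        assert res.sensitivity == 0.0 and res.specificity == 1.0
        assert np.isinf(res.threshold)

    def test_tie_break_prefers_specificity_then_threshold(self):
        # thresholds 2 and 3 both give J_w = 1 is impossible; craft a tie at
        # equal J_w with different specificity instead
        v = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 1, 0, 1], dtype=bool)
        scan = threshold_scan(v, y, 0.5)
        best = optimal_threshold(v, y, 0.5)
        ties = scan.j_w == pytest.approx(best.j_w)
        # the returned point is at least as specific as any tied competitor
        tied = np.flatnonzero(np.abs(scan.j_w - best.j_w) < 1e-12)
        assert best.specificity == pytest.approx(scan.specificity[tied].max())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_threshold([1.0, 2.0], [1, 1], 0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_scan_matches_midpoint_brute_force(self, seed):
        """The observed-value scan attains the same maximum J_w as brute-force
        evaluation of every midpoint threshold (<= 20 subjects, with ties)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 21))
        v = np.round(rng.normal(0, 2, n), 1)  # coarse grid induces ties
        y = rng.random(n) < 0.7
        if y.all() or not y.any():
            y[0] = ~y[0]
        res = optimal_threshold(v, y, 0.1)
        grid = np.sort(np.unique(v))
        cand = np.concatenate(
            [[grid[0] - 1], (grid[:-1] + grid[1:]) / 2, [grid[-1] + 1], grid]
        )
        best = -np.inf
        for theta in cand:
            sens = (v[y] >= theta).mean()
            spec = (v[~y] < theta).mean()
            best = max(best, weighted_youden(sens, spec, 0.1))
        assert res.j_w == pytest.approx(best, abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_and_auc([1, 2, 3, 4], [0, 0, 1, 1], n_boot=0)
        assert roc["auc"] == pytest.approx(1.0)

    def test_all_ties_is_chance(self):
        roc = roc_and_auc([5.0] * 8, [0, 1, 0, 1, 0, 1, 1, 1], n_boot=0)
        assert roc["auc"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_mannwhitney(self, seed):
        rng = np.random.default_rng(seed)
        v = np.round(rng.normal(0, 1, 60), 1)
        y = rng.random(60) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        roc = roc_and_auc(v, y, n_boot=0)
        ranks = rankdata(v)
        n1 = int(y.sum())
        u = ranks[y].sum() - n1 * (n1 + 1) / 2
        assert roc["auc"] == pytest.approx(u / (n1 * (60 - n1)), abs=1e-12)

    def test_trapezoid_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        v = rng.normal(0, 1, 50)
        y = rng.random(50) < 0.6
        roc = roc_and_auc(v, y, n_boot=0)
        assert roc["auc"] == pytest.approx(roc_auc_score(y, v), abs=1e-12)

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 15)])
        y = np.concatenate([np.ones(30, bool), np.zeros(15, bool)])
        r1 = roc_and_auc(v, y, n_boot=500, seed=42)
        r2 = roc_and_auc(v, y, n_boot=500, seed=42)
        assert r1["auc_ci"] == r2["auc_ci"]
        lo, hi = r1["auc_ci"]
        assert lo <= r1["auc"] <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([1.0, 2.0], [1, 1])


class TestKFold:
    def _separable(self, n=48, n_pos=37, seed=0):
        # clustered values: the lowest positive level recurs in every
        # training split, so each fold's threshold separates the test split
        rng = np.random.default_rng(seed)
        v = np.concatenate(
            [rng.choice([5.0, 6.0, 7.0], n_pos), rng.choice([1.0, 2.0], n - n_pos)]
        )
        y = np.concatenate([np.ones(n_pos, bool), np.zeros(n - n_pos, bool)])
        return v, y

    def test_separable_data_perfect_folds(self):
        v, y = self._separable()
        cv = kfold_cv(v, y, k=10, w=0.1, seed=1)
        assert len(cv) == 10
        np.testing.assert_allclose(cv["test_j_w"], 1.0)
        assert (cv["threshold"] > 2).all() and (cv["threshold"] <= 5).all()

    def test_same_seed_reproducible(self):
        v, y = self._separable(seed=5)
        cv1 = kfold_cv(v, y, k=10, seed=7)
        cv2 = kfold_cv(v, y, k=10, seed=7)
        pd.testing.assert_frame_equal(cv1, cv2)

    def test_stratification_balance(self):
        _, y = self._separable()
        cv = kfold_cv(*self._separable(), k=10, seed=3)
        # 11 negatives across 10 folds: every test fold holds 1 or 2
        global_prev = y.mean()
        assert cv["n_test"].sum() == len(y)

    def test_cv_summary_fields(self):
        v, y = self._separable()
        s = summarize_cv(kfold_cv(v, y, k=10, seed=0))
        assert s["threshold_min"] <= s["threshold_max"]
        assert s["j_w_q1"] <= s["j_w_median"] <= s["j_w_q3"]


class TestTimeResolved:
    def _binned(self, value_pos=5.0, value_neg=1.0):
        vals = [value_pos] * 9 + [value_neg] * 3
        y = np.array([1] * 9 + [0] * 3, dtype=bool)
        binned = pd.DataFrame({f"bin{m}": vals for m in range(2, 10)})
        return binned, y

    def test_constant_separable_data_all_bins_perfect(self):
        binned, y = self._binned()
        perf = time_resolved_performance(binned, y, threshold=3.0, k=3, seed=0)
        assert np.allclose(perf["j_w"], 1.0)
        pb = bin_medians(perf)
        assert np.allclose(pb["j_w_median"], 1.0)

    def test_threshold_above_all_values_hits_floor(self):
        binned, y = self._binned()
        perf = time_resolved_performance(binned, y, threshold=100.0, k=3, seed=0)
        assert np.allclose(perf["specificity"], 1.0)
        assert np.allclose(perf["sensitivity"], 0.0)
        assert np.allclose(perf["j_w"], 0.8)

    def test_missing_bin_cells_are_nan(self):
        binned, y = self._binned()
        binned.loc[:, "bin2"] = np.nan
        perf = time_resolved_performance(binned, y, threshold=3.0, k=3, seed=0)
        assert perf.loc[perf["bin"] == "bin2", "j_w"].isna().all()
        assert perf.loc[perf["bin"] == "bin3", "j_w"].notna().all()
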