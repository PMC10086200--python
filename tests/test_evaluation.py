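"""Diagnostics, AUROC rank statistic, matching and group comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from batscan.evaluation import (
    auroc,
    auroc_ci,
    diagnostics,
    group_compare,
    propensity_match,
    proportion_ci,
)
from oracles import brute_auroc


class TestAUROC:
    def test_matches_pair_enumeration_small_n(self, rng):
        for n in (4, 8, 12):
            for _ in range(40):
                scores = np.round(rng.random(n), 1)  # coarse grid forces ties
                labels = rng.integers(0, 2, n)
                if labels.min() == labels.max():
                    continue
                assert auroc(scores, labels) == pytest.approx(brute_auroc(scores, labels))

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        assert auroc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_perfect_and_tied(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_label_swap_symmetry(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        assert auroc(scores, labels) == pytest.approx(1.0 - auroc(scores, 1 - labels))

    def test_ci_contains_point_and_orders(self, rng):
        scores = rng.normal(size=80) + rng.integers(0, 2, 80)
        labels = (scores > 0.5).astype(int)
        labels[:5] = 1 - labels[:5]
        a, lo, hi = auroc_ci(scores, labels)
        assert 0.0 <= lo <= a <= hi <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestDiagnostics:
    def test_hand_confusion_matrix(self):
        """TP=2, FN=0, TN=1, FP=1 -> sens 1.0, spec 0.5, acc 0.75."""
        s = diagnostics([1, 1, 1, 0], [1, 1, 0, 0])
        assert s.metrics["sensitivity"][0] == pytest.approx(1.0)
        assert s.metrics["specificity"][0] == pytest.approx(0.5)
        assert s.metrics["accuracy"][0] == pytest.approx(0.75)
        assert s.tp == 2 and s.fp == 1 and s.tn == 1 and s.fn == 0
        assert s.tp + s.fp + s.tn + s.fn == s.n

    def test_auroc_cutoff_equals_mean_of_sens_spec(self, rng):
        pred = rng.integers(0, 2, 60)
        truth = rng.integers(0, 2, 60)
        if truth.min() == truth.max():
            truth[0] = 1 - truth[0]
        s = diagnostics(pred, truth)
        sens = s.metrics["sensitivity"][0]
        spec = s.metrics["specificity"][0]
        assert s.metrics["auroc_cutoff"][0] == pytest.approx((sens + spec) / 2)

    def test_clopper_pearson_against_scipy_binomtest(self):
        for k, n in ((0, 10), (3, 10), (10, 10), (17, 20)):
            p, lo, hi = proportion_ci(k, n)
            ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
            assert lo == pytest.approx(ci.low, abs=1e-12)
            assert hi == pytest.approx(ci.high, abs=1e-12)

    def test_single_class_truth_raises_for_scores(self):
        with pytest.raises(ValueError, match="single class"):
            diagnostics([1, 0], [1, 1], scores=[0.9, 0.1])


class TestPropensityMatch:
    def _frames(self, case_cov, ctrl_cov):
        cases = pd.DataFrame(case_cov, columns=["age", "weight"])
        cases["patient_id"] = [f"case{i}" for i in range(len(cases))]
        ctrls = pd.DataFrame(ctrl_cov, columns=["age", "weight"])
        ctrls["patient_id"] = [f"ctrl{i}" for i in range(len(ctrls))]
        return cases, ctrls

    def test_identical_rows_all_matched_at_zero_distance(self, rng):
        cov = rng.normal(size=(6, 2))
        cases, ctrls = self._frames(cov, cov)
        res = propensity_match(cases, ctrls, ["age", "weight"], seed=0)
        assert len(res.pairs) == 6
        assert res.unmatched_cases == []
        for cid, kid in res.pairs:
            assert abs(res.propensity[cid] - res.propensity[kid]) <= 1e-9

    def test_caliper_blocks_distant_controls(self, rng):
        # two well-separated but overlapping-enough clouds
        cases, ctrls = self._frames(
            np.array([[1.0, 1.0], [1.1, 0.9], [0.9, 1.1], [30.0, 1.0]]),
            np.array([[1.05, 1.0], [0.95, 1.05], [1.0, 0.95], [1.1, 1.1]]),
        )
        res = propensity_match(cases, ctrls, ["age", "weight"], caliper=0.1, seed=0)
        assert "case3" in res.unmatched_cases  # the outlier finds no control

    def test_greedy_without_replacement(self, rng):
        cov_cases = rng.normal(size=(3, 2))
        cov_ctrls = np.vstack([cov_cases + 0.01, rng.normal(size=(2, 2))])
        cases, ctrls = self._frames(cov_cases, cov_ctrls)
        res = propensity_match(cases, ctrls, ["age", "weight"], seed=1)
        used = [k for _, k in res.pairs]
        assert len(used) == len(set(used))  # 1:1, no control reused

    def test_perfect_separation_rejected(self):
        cases, ctrls = self._frames(
            np.array([[10.0, 1.0]] * 4), np.array([[-10.0, 1.0]] * 4)
        )
        with pytest.raises(ValueError, match="separation|degenerate"):
            propensity_match(cases, ctrls, ["age", "weight"])


class TestGroupCompare:
    def test_identical_groups_rank_test_p_near_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 100.0]  # non-normal
        res = group_compare(a, list(a), kind="continuous")
        assert res.p_value > 0.9

    def test_fisher_exact_equals_hypergeometric_tail(self):
        # 2x2 table [[5,0],[0,5]] -> two-sided p = 2 / C(10,5)
        a = np.array([1] * 5)
        b = np.array([0] * 5)
        res = group_compare(a, b, kind="categorical")
        assert res.test == "fisher"
        assert res.p_value == pytest.approx(2.0 / 252.0)

    def test_zero_cells_route_to_exact_test(self):
        a = np.array([0, 0, 0, 1])
        b = np.array([0, 0, 0, 0])
        res = group_compare(a, b, kind="categorical")
        assert res.test == "fisher"

    def test_large_balanced_table_routes_to_chi2(self, rng):
        a = rng.integers(0, 2, 200)
        b = rng.integers(0, 2, 200)
        assert group_compare(a, b, kind="categorical").test == "chi2"

    def test_normal_data_routes_to_t(self, rng):
        a = rng.normal(0, 1, 300)
        b = rng.normal(0.1, 1, 300)
        assert group_compare(a, b, kind="continuous").test == "t"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0], kind="continuous")
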