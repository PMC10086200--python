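"""ICC filter, Pearson redundancy pruning and LASSO selection."""

import numpy as np
import pandas as pd
import pytest

from batscan.selection import (
    CorrelationPruner,
    ICCFilter,
    LassoSelector,
    icc_two_way_random_single,
    select_features,
)


class TestICC:
    def test_hand_table_matches_anova_mean_squares(self):
        """Frozen 5-depot 2-rater value from the closed-form mean squares
        (independently cross-checked against pingouin ICC(A,1))."""
        r = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 9.0], [2.0, 6.0], [7.0, 8.0]])
        assert icc_two_way_random_single(r) == pytest.approx(-0.5497382198952883, abs=1e-9)

    def test_matches_pingouin_on_random_tables(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(5):
            r = rng.normal(size=(8, 2))
            r[:, 1] += 0.5 * r[:, 0]
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(8), 2),
                "raters": np.tile(np.arange(2), 8),
                "ratings": r.ravel(),
            })
            expected = pg.intraclass_corr(df, targets="targets", raters="raters",
                                          ratings="ratings").set_index("Type").loc["ICC(A,1)", "ICC"]
            assert icc_two_way_random_single(r) == pytest.approx(expected, abs=1e-9)

    def test_identical_raters_give_one(self, rng):
        X = rng.normal(size=(10, 4))
        f = ICCFilter().fit(X, X.copy())
        np.testing.assert_allclose(f.icc_, 1.0)
        assert f.get_support().all()

    def test_uncorrelated_raters_removed(self, rng):
        X1 = rng.normal(size=(200, 3))
        X2 = rng.normal(size=(200, 3))  # independent noise
        f = ICCFilter(threshold=0.80).fit(X1, X2)
        assert (np.abs(f.icc_) < 0.3).all()
        assert not f.get_support().any()

    def test_too_few_depots_rejected(self, rng):
        with pytest.raises(ValueError):
            ICCFilter().fit(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestPruner:
    def test_weaker_duplicate_removed(self, rng):
        y = rng.integers(0, 2, size=60).astype(float)
        strong = y + 0.1 * rng.normal(size=60)
        dup = strong.copy()          # exact duplicate, so |r| = 1
        weak_label = strong + 2.0 * rng.normal(size=60)
        X = np.column_stack([strong, dup, weak_label])
        p = CorrelationPruner(0.90).fit(X, y, feature_names=["strong", "dup", "weak"])
        # one of the duplicated pair must go; the unrelated feature stays
        assert p.get_support().sum() == 2
        assert p.get_support()[2]
        assert p.get_support()[0] != p.get_support()[1]

    def test_nothing_removed_below_threshold(self, rng):
        X = rng.normal(size=(80, 5))
        y = rng.integers(0, 2, 80).astype(float)
        p = CorrelationPruner(0.90).fit(X, y)
        assert p.get_support().all()

    def test_four_feature_known_structure_matches_greedy_enumeration(self, rng):
        """Hand-built correlation structure: the greedy rule's survivors
        match a by-hand application of the scan order."""
        n = 500
        y = rng.integers(0, 2, n).astype(float)
        a = y + 0.3 * rng.normal(size=n)            # informative
        b = a + 0.01 * rng.normal(size=n)           # near-duplicate of a, weaker
        c = rng.normal(size=n)                      # noise
        d = c + 0.01 * rng.normal(size=n)           # near-duplicate of c
        X = np.column_stack([a, b, c, d])
        names = ["a", "b", "c", "d"]
        p = CorrelationPruner(0.90).fit(X, y, feature_names=names)

        # by hand: |r(a,b)| and |r(c,d)| exceed 0.9; within each pair the
        # one with lower |point-biserial vs y| goes
        def pb(v):
            return abs(np.corrcoef(v, y)[0, 1])

        expected = np.ones(4, dtype=bool)
        expected[0 if pb(a) < pb(b) else 1] = False
        expected[2 if pb(c) < pb(d) else 3] = False
        np.testing.assert_array_equal(p.get_support(), expected)

    def test_constant_feature_correlation_defined_zero(self, rng):
        X = np.column_stack([np.full(50, 3.0), rng.normal(size=50)])
        y = rng.integers(0, 2, 50).astype(float)
        p = CorrelationPruner(0.90).fit(X, y)
        assert p.get_support().all()  # constant has r=0 with everything


class TestLasso:
    def test_recovers_separating_feature_among_noise(self, rng):
        n = 120
        y = rng.integers(0, 2, n).astype(float)
        signal = y * 2 - 1 + 0.2 * rng.normal(size=n)
        X = np.column_stack([signal] + [rng.normal(size=n) for _ in range(8)])
        sel = LassoSelector(random_state=0).fit(X, y)
        assert sel.get_support()[0]
        assert sel.get_support().sum() < 9

    def test_huge_penalty_kills_everything(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 2, 40).astype(float)
        with pytest.raises(ValueError, match="grid"):
            LassoSelector(alphas=[1e6]).fit(X, y)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            LassoSelector().fit(rng.normal(size=(20, 3)), np.ones(20))

    def test_scaling_invariance_of_selection(self, rng):
        n = 100
        y = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([y + 0.3 * rng.normal(size=n),
                             rng.normal(size=n), rng.normal(size=n)])
        s1 = LassoSelector(random_state=1).fit(X, y).get_support()
        X2 = X * np.array([1000.0, 0.01, 5.0])
        s2 = LassoSelector(random_state=1).fit(X2, y).get_support()
        np.testing.assert_array_equal(s1, s2)


def test_cascade_monotone_and_reasons(rng):
    n, p = 80, 12
    y = rng.integers(0, 2, n).astype(float)
    base = rng.normal(size=(n, p))
    base[:, 0] += 2 * y                      # informative
    base[:, 1] = base[:, 0] + 0.01 * rng.normal(size=n)  # redundant twin
    names = [f"feat{j:02d}" for j in range(p)]
    t1 = pd.DataFrame(base, columns=names)
    noisy = base + 0.05 * rng.normal(size=base.shape)
    noisy[:, 5] = rng.normal(size=n)         # irreproducible feature
    t2 = pd.DataFrame(noisy, columns=names)

    report = select_features(t1, t2, y, names, random_state=0)
    assert report.n_final <= report.n_post_prune <= report.n_post_icc <= p
    assert report.removal_reason["feat05"] == "icc"
    reasons = set(report.removal_reason.values())
    assert reasons <= {"", "icc", "redundancy", "lasso"}
    # the informative pair contributes exactly one survivor past pruning
    kept_pair = [f for f in ("feat00", "feat01") if report.removal_reason[f] in ("", "lasso")]
    assert len(kept_pair) == 1
    assert "feat00" in report.final_features or "feat01" in report.final_features
    assert report.final_features == [f for f in names if report.removal_reason[f] == ""]
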