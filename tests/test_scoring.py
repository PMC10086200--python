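"""Depot model, Youden cutoff, strict-positivity rule, patient criteria."""

import itertools

import numpy as np
import pandas as pd
import pytest

from batscan.evaluation import auroc
from batscan.scoring import (
    DepotScoreModel,
    call_cohort,
    call_patient,
    classify_depot,
    youden_cutoff,
)
from oracles import brute_patient_criteria, brute_youden


class TestYouden:
    def test_separable_scores_attain_perfect_j(self):
        """(.1,.2,.8,.9) vs (0,0,1,1): J=1 attainable; with the strict
        'score > t' rule the attaining observed threshold is 0.2, and
        classification at that cutoff is perfect."""
        rs, j, degen = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], full=True)
        assert rs == pytest.approx(0.2)
        assert j == pytest.approx(1.0) and not degen
        pred = np.array([0.1, 0.2, 0.8, 0.9]) > rs
        assert pred.tolist() == [False, False, True, True]

    def test_matches_brute_force_enumeration(self, rng):
        for n in (4, 7, 12):
            for _ in range(30):
                scores = np.round(rng.random(n), 2)
                labels = rng.integers(0, 2, n)
                if labels.min() == labels.max():
                    continue
                t, j, degen = youden_cutoff(scores, labels, full=True)
                bt, bj = brute_youden(scores, labels)
                assert t == pytest.approx(bt)
                assert j == pytest.approx(bj)

    def test_inverted_scores_flagged_degenerate(self):
        t, j, degen = youden_cutoff([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1], full=True)
        assert j <= 0 and degen

    def test_all_tied_scores_degenerate(self):
        t, j, degen = youden_cutoff([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1], full=True)
        assert j == pytest.approx(0.0) and degen

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff([0.1, 0.9], [1, 1])


def _toy_features(rng, n=80, sep=3.0):
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 3))
    X[:, 0] += sep * y
    return pd.DataFrame(X, columns=["f0", "f1", "f2"]), y


class TestDepotModel:
    def test_separable_training_perfect_at_cutoff(self, rng):
        X, y = _toy_features(rng, sep=8.0)
        m = DepotScoreModel(random_state=0, feature_names=list(X.columns))
        m.fit(X.to_numpy(), y)
        pred = m.predict(X.to_numpy())
        assert (pred == y).mean() == 1.0
        assert 0.0 < m.cutoff_ < 1.0

    def test_scores_in_unit_interval_and_seeded(self, rng):
        X, y = _toy_features(rng)
        m1 = DepotScoreModel(random_state=7, feature_names=list(X.columns)).fit(X.to_numpy(), y)
        m2 = DepotScoreModel(random_state=7, feature_names=list(X.columns)).fit(X.to_numpy(), y)
        s1 = m1.radiomics_score(X.to_numpy())
        s2 = m2.radiomics_score(X.to_numpy())
        np.testing.assert_array_equal(s1, s2)
        assert (s1 >= 0).all() and (s1 <= 1).all()

    def test_label_permutation_gives_chance_auroc(self, rng):
        X, y = _toy_features(rng, n=200, sep=3.0)
        y_perm = rng.permutation(y)
        half = 100
        m = DepotScoreModel(random_state=0, feature_names=list(X.columns))
        m.fit(X.to_numpy()[:half], y_perm[:half])
        a = auroc(m.radiomics_score(X.to_numpy()[half:]), y_perm[half:])
        assert 0.35 < a < 0.65

    def test_single_class_rejected(self, rng):
        X, _ = _toy_features(rng)
        with pytest.raises(ValueError):
            DepotScoreModel().fit(X.to_numpy(), np.zeros(len(X)))

    def test_classify_depot_strict_inequality(self, rng):
        X, y = _toy_features(rng, sep=8.0)
        m = DepotScoreModel(random_state=0, feature_names=list(X.columns)).fit(X.to_numpy(), y)
        m.cutoff_ = 0.30
        row = X.iloc[0].copy()

        rs, pos = classify_depot(m, row)
        assert pos == (rs > 0.30)
        # a depot scoring exactly at the cutoff is negative
        assert (0.30 > m.cutoff_) is False

    def test_missing_feature_named(self, rng):
        X, y = _toy_features(rng)
        m = DepotScoreModel(random_state=0, feature_names=list(X.columns)).fit(X.to_numpy(), y)
        with pytest.raises(KeyError, match="f2"):
            classify_depot(m, X.iloc[0].drop("f2"))


def _patient_df(rows):
    return pd.DataFrame(
        [{"patient_id": "P0", "depot_id": f"P0_d{i:02d}", "region": r,
          "laterality": l, "positive": p} for i, (r, l, p) in enumerate(rows)]
    )


class TestPatientCriteria:
    def test_single_unilateral_positive(self):
        call = call_patient(_patient_df([
            ("cervical", "left", True), ("cervical", "right", False),
            ("supraclavicular", "left", False), ("supraclavicular", "right", False),
        ]))
        assert call.criterion1_positive and not call.criterion2_positive

    def test_symmetric_pair_positive(self):
        call = call_patient(_patient_df([
            ("supraclavicular", "left", True), ("supraclavicular", "right", True),
        ]))
        assert call.criterion1_positive and call.criterion2_positive
        assert call.symmetric_pairs

    def test_single_mediastinal_positive(self):
        call = call_patient(_patient_df([
            ("cervical", "left", False), ("cervical", "right", False),
            ("mediastinal", "midline", True),
        ]))
        assert call.criterion2_positive

    def test_no_positive_depots(self):
        call = call_patient(_patient_df([
            ("axillary", "left", False), ("axillary", "right", False),
        ]))
        assert not call.criterion1_positive and not call.criterion2_positive

    def test_missing_partner_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            call_patient(_patient_df([("cervical", "left", True)]))

    def test_exhaustive_64_patterns_match_rule_oracle(self):
        """All 2^6 positivity patterns of a 6-depot patient vs the
        brute-force reading of the two criteria; criterion 2 implies 1."""
        layout = [("cervical", "left"), ("cervical", "right"),
                  ("supraclavicular", "left"), ("supraclavicular", "right"),
                  ("mediastinal", "midline"), ("mediastinal", "midline")]
        for bits in itertools.product([False, True], repeat=6):
            rows = [(r, l, b) for (r, l), b in zip(layout, bits)]
            call = call_patient(_patient_df(rows))
            c1, c2 = brute_patient_criteria(rows)
            assert call.criterion1_positive == c1
            assert call.criterion2_positive == c2
            assert not (call.criterion2_positive and not call.criterion1_positive)

    def test_call_cohort_groups_by_patient(self):
        df = _patient_df([("cervical", "left", True), ("cervical", "right", True)])
        df2 = df.copy()
        df2["patient_id"] = "P1"
        df2["positive"] = False
        out = call_cohort(pd.concat([df, df2])).set_index("patient_id")
        assert bool(out.loc["P0", "criterion2_positive"])
        assert not bool(out.loc["P1", "criterion1_positive"])
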