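"""Diagnostic metrics, ROC analysis, propensity matching, group tests.

Proportion metrics carry exact (Clopper-Pearson) 95% CIs.  AUROC is the
tie-corrected rank statistic (the concordant-pair fraction, ties counting
half) with a DeLong-style placement variance for its CI.  The
"AUROC-at-cutoff" of a binarized prediction equals
(sensitivity + specificity) / 2.

Propensity matching is 1:1 greedy nearest-neighbor without replacement on
the logistic propensity, in seeded random case order, with a caliper on
the propensity scale.  Group comparison routes continuous data through a
Kolmogorov-Smirnov normality screen to a t-test or Mann-Whitney test, and
categorical data to chi-squared or Fisher's exact test by the
expected-count rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression


# ----------------------------------------------------------------- ROC ----

def auroc(scores, labels) -> float:
    """Concordant-pair fraction (ties count 1/2), via midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUROC needs both classes")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def _delong_variance(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement values
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > y) + 0.5 * np.sum(pos == y)) / m for y in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def auroc_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUROC with DeLong-variance normal-approximation CI, clipped to [0,1]."""
    a = auroc(scores, labels)
    se = np.sqrt(_delong_variance(scores, labels))
    z = stats.norm.ppf(1 - alpha / 2)
    return a, float(np.clip(a - z * se, 0, 1)), float(np.clip(a + z * se, 0, 1))


def proportion_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float, float]:
    """Exact Clopper-Pearson interval for a binomial proportion."""
    if n == 0:
        return np.nan, np.nan, np.nan
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return k / n, lo, hi


# --------------------------------------------------------- diagnostics ----

@dataclass
class DiagnosticSummary:
    level: str                      # 'depot' | 'patient'
    cohort: str
    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict[str, tuple[float, float, float]]  # name -> (point, lo, hi)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"level": self.level, "cohort": self.cohort, "metric": k,
                 "value": v[0], "ci_low": v[1], "ci_high": v[2]}
                for k, v in self.metrics.items()]
        return pd.DataFrame(rows)


def diagnostics(predictions, truth, scores=None, level: str = "depot",
                cohort: str = "") -> DiagnosticSummary:
    """Confusion-matrix metrics with exact CIs; AUROC when scores given.

    ``predictions`` are binary calls; ``scores`` (optional) the continuous
    radiomics scores for the rank AUROC.  AUROC-at-cutoff is the rank
    AUROC of the binary calls themselves, i.e. (sens + spec) / 2.
    """
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(truth, dtype=int)
    if pred.shape != y.shape:
        raise ValueError("predictions and truth are not aligned")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    metrics = {
        "sensitivity": proportion_ci(tp, tp + fn),
        "specificity": proportion_ci(tn, tn + fp),
        "ppv": proportion_ci(tp, tp + fp),
        "npv": proportion_ci(tn, tn + fn),
        "accuracy": proportion_ci(tp + tn, len(y)),
    }
    both_classes = len(np.unique(y)) == 2
    if both_classes:
        metrics["auroc_cutoff"] = auroc_ci(pred.astype(float), y)
        if scores is not None:
            metrics["auroc"] = auroc_ci(np.asarray(scores, dtype=float), y)
    elif scores is not None:
        raise ValueError("AUROC undefined: truth contains a single class")
    return DiagnosticSummary(level, cohort, len(y), tp, fp, tn, fn, metrics)


# ------------------------------------------------------------ matching ----

@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]
    propensity_coef: np.ndarray
    propensity_intercept: float
    caliper: float
    unmatched_cases: list[str]
    unmatched_controls: list[str]
    propensity: dict[str, float]


def propensity_match(cases: pd.DataFrame, controls: pd.DataFrame, covariates,
                     caliper: float = 0.1, seed: int = 0,
                     id_column: str = "patient_id") -> MatchResult:
    """1:1 greedy nearest-neighbor matching without replacement.

    The propensity is a logistic regression of case membership on the
    covariates; cases are visited in seeded random order and matched to
    the nearest unused control within the caliper (propensity scale).
    """
    covariates = list(covariates)
    X = np.vstack([cases[covariates].to_numpy(float), controls[covariates].to_numpy(float)])
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    mu, sd = X.mean(0), X.std(0)
    sd[sd == 0] = 1.0
    lr = LogisticRegression(max_iter=2000, C=1e6)  # near-unpenalized fit
    lr.fit((X - mu) / sd, y)
    p = lr.predict_proba((X - mu) / sd)[:, 1]
    if p[y == 1].min() > 1 - 1e-3 and p[y == 0].max() < 1e-3:
        # no common support: every case is (near-)certainly a case
        raise ValueError("degenerate propensity fit (perfect separation); check covariates")
    p_case = p[: len(cases)]
    p_ctrl = p[len(cases):]
    case_ids = cases[id_column].astype(str).tolist()
    ctrl_ids = controls[id_column].astype(str).tolist()

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    used = np.zeros(len(controls), dtype=bool)
    pairs: list[tuple[str, str]] = []
    unmatched = []
    for i in order:
        d = np.abs(p_ctrl - p_case[i])
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= caliper:
            used[j] = True
            pairs.append((case_ids[i], ctrl_ids[j]))
        else:
            unmatched.append(case_ids[i])
    prop = {pid: float(v) for pid, v in zip(case_ids + ctrl_ids, np.concatenate([p_case, p_ctrl]))}
    return MatchResult(pairs, lr.coef_[0], float(lr.intercept_[0]), caliper,
                       sorted(unmatched), [c for c, u in zip(ctrl_ids, used) if not u], prop)


# ------------------------------------------------------- group compare ----

@dataclass
class GroupTest:
    kind: str
    test: str
    statistic: float
    p_value: float


def group_compare(group_a, group_b, kind: str = "continuous") -> GroupTest:
    """Two-group comparison with the field's standard routing.

    Continuous: Kolmogorov-Smirnov normality screen on each group; both
    normal -> Student t-test, otherwise Mann-Whitney U.  Categorical
    (values are category codes): chi-squared unless any expected count
    < 5, then Fisher's exact (2x2 only).
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if kind == "continuous":
        a = a.astype(float)
        b = b.astype(float)
        normal = True
        for g in (a, b):
            if g.std(ddof=1) == 0:
                normal = False
                break
            p = stats.kstest((g - g.mean()) / g.std(ddof=1), "norm").pvalue
            if p < 0.05:
                normal = False
        if normal:
            s, p = stats.ttest_ind(a, b)
            return GroupTest("continuous", "t", float(s), float(p))
        s, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return GroupTest("continuous", "mannwhitney", float(s), float(p))
    if kind == "categorical":
        cats = np.unique(np.concatenate([a, b]))
        table = np.array([[np.sum(g == c) for c in cats] for g in (a, b)])
        if table.shape[1] == 1:  # no variation at all: nothing to test
            return GroupTest("categorical", "none", 0.0, 1.0)
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            if table.shape != (2, 2):
                raise ValueError("Fisher's exact routing implemented for 2x2 tables only")
            s, p = stats.fisher_exact(table)
            return GroupTest("categorical", "fisher", float(s), float(p))
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupTest("categorical", "chi2", float(chi2), float(p))
    raise ValueError(f"unknown kind {kind!r}")
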