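"""Three-stage feature-reduction cascade.

1. Reproducibility: two-way random, absolute-agreement, single-measures
   intraclass correlation (ICC(A,1)) between two segmentations of every
   depot; features with ICC < 0.80 are dropped.
2. Redundancy: greedy pruning of pairs with |Pearson r| > 0.90, scanning
   pairs by descending |r| (ties broken lexicographically); within a pair
   the feature with the lower |point-biserial correlation with the BAT
   label| is removed.
3. Sparsity: L1-penalized linear regression on the 0/1 label; the penalty
   is chosen by cross-validated AUROC on a fixed grid with a seeded fold
   split, and features with nonzero coefficients survive.

The three stages are sklearn transformers (``fit``/``transform``/
``get_support``) so they compose in a ``Pipeline``; :func:`select_features`
runs the cascade on depot feature tables and produces a
:class:`SelectionReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import Lasso
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------- ICC ----

def icc_two_way_random_single(ratings: np.ndarray) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single
    measures, from the classic ANOVA mean squares.

    ``ratings`` is (n_subjects, k_raters).  Degenerate inputs: exactly
    identical columns give 1.0; otherwise a vanishing denominator gives 0.
    """
    r = np.asarray(ratings, dtype=float)
    n, k = r.shape
    if n < 3 or k < 2:
        raise ValueError("ICC needs >= 3 subjects and >= 2 raters")
    if np.allclose(r, r[:, [0]]):
        return 1.0
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((r - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if abs(denom) < 1e-30:
        return 0.0
    return float((msr - mse) / denom)


class ICCFilter(BaseEstimator, TransformerMixin):
    """Drop features whose two-segmentation ICC(A,1) falls below threshold.

    ``fit(X, X_repeat)`` takes the same feature matrix measured under two
    segmentations of the same depots (rows aligned).
    """

    def __init__(self, threshold: float = 0.80):
        self.threshold = threshold

    def fit(self, X, X_repeat=None):
        if X_repeat is None:
            raise ValueError("ICCFilter.fit needs the second-segmentation table")
        X = np.asarray(X, dtype=float)
        X2 = np.asarray(X_repeat, dtype=float)
        if X.shape != X2.shape:
            raise ValueError("the two tables must cover the same depots and features")
        if X.shape[0] < 3:
            raise ValueError("ICC needs at least 3 depots")
        self.icc_ = np.array([
            icc_two_way_random_single(np.column_stack([X[:, j], X2[:, j]]))
            for j in range(X.shape[1])
        ])
        self.support_ = self.icc_ >= self.threshold
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


# ------------------------------------------------------------- pruning ----

def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    # constant columns have correlation defined as 0
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """Greedy redundancy pruning of highly correlated feature pairs.

    Pairs with |r| > threshold are scanned by descending |r| (ties broken
    lexicographically by feature name); within a pair the feature with
    the lower |point-biserial correlation with the label| is removed, and
    pairs with an already-removed member are skipped.
    """

    def __init__(self, r_threshold: float = 0.90):
        self.r_threshold = r_threshold

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        p = X.shape[1]
        names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
        std = X.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False) if p > 1 else np.ones((1, 1))
        corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
        label_corr = np.array([abs(_safe_corr(X[:, j], y)) for j in range(p)])

        pairs = [
            (abs(corr[a, b]), min(names[a], names[b]), max(names[a], names[b]), a, b)
            for a in range(p) for b in range(a + 1, p)
            if abs(corr[a, b]) > self.r_threshold
        ]
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        removed = np.zeros(p, dtype=bool)
        for _r, _na, _nb, a, b in pairs:
            if removed[a] or removed[b]:
                continue
            if label_corr[a] < label_corr[b]:
                removed[a] = True
            elif label_corr[b] < label_corr[a]:
                removed[b] = True
            else:  # tie: drop the lexicographically later name
                removed[b if names[b] > names[a] else a] = True
        self.support_ = ~removed
        self.label_corr_ = label_corr
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


# --------------------------------------------------------------- LASSO ----

class LassoSelector(BaseEstimator, TransformerMixin):
    """L1-penalized linear regression on the binary label.

    Features are standardized internally; the penalty is chosen from a
    fixed log-spaced grid by mean cross-validated AUROC of the linear
    predictions (stratified folds, seeded).  Features with nonzero
    coefficients at the chosen penalty form the selection.
    """

    def __init__(self, alphas=None, cv_folds: int = 5, random_state: int = 0):
        self.alphas = alphas
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("LASSO selection needs both classes")
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        Z = (X - mean) / std
        alphas = np.logspace(-3, 0, 25) if self.alphas is None else np.asarray(self.alphas)

        skf = StratifiedKFold(n_splits=self.cv_folds, shuffle=True, random_state=self.random_state)
        splits = list(skf.split(Z, y))
        cv_auc = np.zeros(len(alphas))
        for i, alpha in enumerate(alphas):
            aucs = []
            for tr, te in splits:
                model = Lasso(alpha=alpha, max_iter=5000)
                model.fit(Z[tr], y[tr])
                pred = model.predict(Z[te])
                if len(np.unique(y[te])) < 2 or np.allclose(pred, pred[0]):
                    aucs.append(0.5)
                else:
                    aucs.append(roc_auc_score(y[te], pred))
            cv_auc[i] = np.mean(aucs)
        best = int(np.argmax(cv_auc))
        final = Lasso(alpha=alphas[best], max_iter=10000)
        final.fit(Z, y)
        self.alphas_ = alphas
        self.cv_auc_ = cv_auc
        self.alpha_ = float(alphas[best])
        self.coef_ = final.coef_
        self.support_ = final.coef_ != 0
        if not self.support_.any():
            raise ValueError(
                "LASSO kept no features at any grid penalty; widen the grid "
                "toward weaker penalties"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


# -------------------------------------------------------------- report ----

@dataclass
class SelectionReport:
    """Provenance of the full cascade for every feature in the census."""

    feature_names: list[str]
    icc: dict[str, float]
    removal_reason: dict[str, str]     # '' when kept
    n_input: int
    n_post_icc: int
    n_post_prune: int
    n_final: int
    lasso_alpha: float
    lasso_alphas: list[float]
    lasso_cv_auc: list[float]
    final_features: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "icc": [self.icc[f] for f in self.feature_names],
            "kept": [self.removal_reason[f] == "" for f in self.feature_names],
            "removal_reason": [self.removal_reason[f] for f in self.feature_names],
        })

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "counts": {"input": self.n_input, "post_icc": self.n_post_icc,
                           "post_prune": self.n_post_prune, "final": self.n_final},
                "lasso_alpha": self.lasso_alpha,
                "final_features": self.final_features,
            }, fh, indent=2)


def select_features(
    table_rater1: pd.DataFrame,
    table_rater2: pd.DataFrame,
    labels: np.ndarray,
    feature_names: list[str],
    icc_threshold: float = 0.80,
    r_threshold: float = 0.90,
    cv_folds: int = 5,
    random_state: int = 0,
) -> SelectionReport:
    """Run the full ICC -> Pearson -> LASSO cascade on depot tables."""
    X1 = table_rater1[feature_names].to_numpy(dtype=float)
    X2 = table_rater2[feature_names].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float)

    iccf = ICCFilter(icc_threshold).fit(X1, X2)
    names_icc = [f for f, keep in zip(feature_names, iccf.get_support()) if keep]
    X_icc = iccf.transform(X1)

    pruner = CorrelationPruner(r_threshold).fit(X_icc, y, feature_names=names_icc)
    names_pruned = [f for f, keep in zip(names_icc, pruner.get_support()) if keep]
    X_pruned = pruner.transform(X_icc)

    lasso = LassoSelector(cv_folds=cv_folds, random_state=random_state).fit(X_pruned, y)
    final = [f for f, keep in zip(names_pruned, lasso.get_support()) if keep]

    reason = {}
    for f in feature_names:
        if f not in names_icc:
            reason[f] = "icc"
        elif f not in names_pruned:
            reason[f] = "redundancy"
        elif f not in final:
            reason[f] = "lasso"
        else:
            reason[f] = ""
    return SelectionReport(
        feature_names=list(feature_names),
        icc={f: float(v) for f, v in zip(feature_names, iccf.icc_)},
        removal_reason=reason,
        n_input=len(feature_names),
        n_post_icc=len(names_icc),
        n_post_prune=len(names_pruned),
        n_final=len(final),
        lasso_alpha=lasso.alpha_,
        lasso_alphas=[float(a) for a in lasso.alphas_],
        lasso_cv_auc=[float(a) for a in lasso.cv_auc_],
        final_features=final,
    )
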