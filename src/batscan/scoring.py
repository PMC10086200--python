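"""Depot classifier, radiomics score, Youden cutoff and patient criteria.

The depot model is an RBF-kernel support vector machine with a
median-heuristic bandwidth, balanced class weights, and a held-out
logistic (Platt) mapping of the margin to a radiomics score RS in [0, 1].
The positivity cutoff RS* is the Youden optimum on the training scores:
candidate cutoffs are the observed scores, each evaluated with the same
strict rule used for classification ("positive iff score > t"), and ties
go to the highest threshold (favoring specificity).  Depot classification
follows the printed strict rule: positive iff RS > RS*.

Patient-level diagnosis applies two criteria: (1) at least one positive
depot; (2) at least one bilateral region (cervical / supraclavicular /
axillary) with both left and right depots positive, or at least one
positive mediastinal depot.  Criterion 2 positivity implies criterion 1
positivity, so over any cohort sensitivity can only drop and specificity
can only rise going from criterion 1 to criterion 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .grid import BILATERAL_REGIONS


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF gamma = 1 / median squared pairwise distance (on a subsample)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n > 500:
        idx = np.linspace(0, n - 1, 500).astype(int)
        X = X[idx]
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    med = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    if med <= 0:
        return 1.0 / max(X.shape[1], 1)
    return 1.0 / med


class DepotScoreModel(ClassifierMixin, BaseEstimator):
    """Kernel SVM with calibrated radiomics score and Youden cutoff.

    sklearn-compatible: ``fit(X, y)``, ``predict_proba`` (column 1 is the
    radiomics score RS), ``predict`` (RS > cutoff_), plus fitted
    attributes ``cutoff_``, ``gamma_``, ``feature_names_``.
    """

    def __init__(self, C: float = 1.0, calibration_folds: int = 3,
                 random_state: int = 0, feature_names=None):
        self.C = C
        self.calibration_folds = calibration_folds
        self.random_state = random_state
        self.feature_names = feature_names

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        self.classes_ = classes
        scaler = StandardScaler().fit(X)
        self.gamma_ = median_heuristic_gamma(scaler.transform(X))
        base = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=self.C, gamma=self.gamma_,
                        class_weight="balanced", random_state=self.random_state)),
        ])
        cv = StratifiedKFold(n_splits=self.calibration_folds, shuffle=True,
                             random_state=self.random_state)
        self.model_ = CalibratedClassifierCV(base, method="sigmoid", cv=cv)
        self.model_.fit(X, y)
        self.feature_names_ = list(self.feature_names) if self.feature_names is not None else None
        scores = self.model_.predict_proba(X)[:, 1]
        self.cutoff_, self.youden_j_, self.cutoff_degenerate_ = youden_cutoff(scores, y, full=True)
        return self

    def radiomics_score(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        rs = self.radiomics_score(X)
        return np.column_stack([1 - rs, rs])

    def predict(self, X) -> np.ndarray:
        return (self.radiomics_score(X) > self.cutoff_).astype(int)

    def to_json(self, path: str) -> None:
        check_is_fitted(self, "model_")
        with open(path, "w") as fh:
            json.dump({
                "kind": "rbf-svm+platt",
                "C": self.C,
                "gamma": self.gamma_,
                "cutoff": float(self.cutoff_),
                "youden_j": float(self.youden_j_),
                "feature_names": self.feature_names_,
                "random_state": self.random_state,
            }, fh, indent=2)


def train_model(features: pd.DataFrame, labels, feature_names, seed: int = 0) -> DepotScoreModel:
    """Convenience wrapper: fit the depot model on a feature table."""
    X = features[list(feature_names)].to_numpy(dtype=float)
    return DepotScoreModel(random_state=seed, feature_names=feature_names).fit(X, np.asarray(labels))


def youden_cutoff(scores, labels, full: bool = False):
    """Youden-optimal cutoff over the observed scores.

    J(t) = sensitivity + specificity - 1 with the same strict rule used
    for classification ("positive iff score > t"); the highest-J
    threshold is returned, ties broken toward the higher threshold
    (favoring specificity).  A degenerate flag marks J <= 0 (useless or
    inverted scores).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes are needed to place a cutoff")
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):
        pred = scores > t
        j = (pred & (labels == 1)).sum() / n_pos + (~pred & (labels == 0)).sum() / n_neg - 1
        if j > best_j or (j == best_j and (best_t is None or t > best_t)):
            best_t, best_j = float(t), float(j)
    degenerate = best_j <= 0
    if full:
        return best_t, best_j, degenerate
    return best_t


def classify_depot(model: DepotScoreModel, features: pd.Series | pd.DataFrame):
    """RS and positivity (strict RS > RS*) for one depot's feature vector."""
    check_is_fitted(model, "model_")
    names = model.feature_names_
    if names is None:
        raise ValueError("model was trained without feature names")
    row = features if isinstance(features, pd.DataFrame) else features.to_frame().T
    missing = [f for f in names if f not in row.columns]
    if missing:
        raise KeyError(f"feature vector is missing model features: {missing}")
    rs = float(model.radiomics_score(row[names].to_numpy(dtype=float))[0])
    return rs, rs > model.cutoff_


@dataclass
class PatientCall:
    patient_id: str
    criterion1_positive: bool
    criterion2_positive: bool
    positive_depots: list[str] = field(default_factory=list)
    symmetric_pairs: list[tuple[str, str]] = field(default_factory=list)
    positive_mediastinal: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.criterion2_positive and not self.criterion1_positive:
            raise ValueError("criterion 2 positivity implies criterion 1 positivity")


def call_patient(depot_calls: pd.DataFrame, patient_id: str | None = None) -> PatientCall:
    """Apply both patient criteria to one patient's depot calls.

    ``depot_calls`` needs columns depot_id, region, laterality, positive
    (and patient_id unless given).  Bilateral regions must come in
    complete left-right pairs.
    """
    df = depot_calls
    if patient_id is None:
        ids = df["patient_id"].unique()
        if len(ids) != 1:
            raise ValueError("pass a single patient's calls or a patient_id")
        patient_id = str(ids[0])
    for region in BILATERAL_REGIONS:
        sub = df[df["region"] == region]
        if len(sub) and set(sub["laterality"]) != {"left", "right"}:
            raise ValueError(f"{patient_id}: bilateral region {region} lacks a left-right pair")

    positive = df[df["positive"].astype(bool)]
    crit1 = len(positive) > 0

    pairs: list[tuple[str, str]] = []
    for region in BILATERAL_REGIONS:
        sub = positive[positive["region"] == region]
        left = sub[sub["laterality"] == "left"]["depot_id"].tolist()
        right = sub[sub["laterality"] == "right"]["depot_id"].tolist()
        if left and right:
            pairs.append((left[0], right[0]))
    medial = positive[positive["region"] == "mediastinal"]["depot_id"].tolist()
    crit2 = bool(pairs) or bool(medial)

    return PatientCall(patient_id, crit1, crit2, positive["depot_id"].tolist(), pairs, medial)


def call_cohort(depot_calls: pd.DataFrame) -> pd.DataFrame:
    """Patient calls for every patient in a depot-call table."""
    rows = []
    for pid, sub in depot_calls.groupby("patient_id", sort=True):
        c = call_patient(sub, str(pid))
        rows.append({"patient_id": c.patient_id,
                     "criterion1_positive": c.criterion1_positive,
                     "criterion2_positive": c.criterion2_positive,
                     "n_positive_depots": len(c.positive_depots)})
    return pd.DataFrame(rows)
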