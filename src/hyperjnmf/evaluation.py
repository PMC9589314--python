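"""Baseline comparison and downstream surgery-classification harness.

Two evaluation stages:

1. ``compare_algorithms`` runs plain joint NMF and the full multi-constraint
   model from the *same* SVD initialization for a fixed iteration budget
   (100 by default) and reports relative reconstruction error and the common
   l1 norm ||W||_1 + ||H1||_1 + ||H2||_1 — the anti-noise comparison.

2. ``classify_patients`` feeds selected features (or any sample-by-feature
   matrix) to a random forest, RBF-SVM or logistic regression with a small
   fixed hyperparameter grid searched by cross-validation on a stratified
   75/25 split, and reports the test-set ROC curve and AUC. Label 2
   (surgical) is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_model import DiagnosisVector, ModalityMatrix, ValidationError
from .factorization import FactorizationParams, FactorizationResult, fit, jnmf_fit, relative_error
from .initialization import svd_init

__all__ = ["ComparisonReport", "ClassificationReport", "compare_algorithms", "classify_patients"]


@dataclass
class ComparisonReport:
    table: pd.DataFrame  # rows: jnmf, full; cols: reconstruction_error, l1_norm, n_iter
    n_iter: int
    jnmf_result: FactorizationResult
    full_result: FactorizationResult


@dataclass
class ClassificationReport:
    classifier: str
    best_params: dict
    seed: int
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_train: int
    n_test: int


def _l1_norm(res: FactorizationResult) -> float:
    return float(res.W.sum() + res.H1.sum() + res.H2.sum())


def compare_algorithms(
    x1,
    x2,
    d,
    a,
    b1,
    b2,
    params: FactorizationParams,
    n_iter: int = 100,
) -> ComparisonReport:
    """Run both algorithms for exactly ``n_iter`` iterations from shared init.

    tol is disabled (set to 0) so both consume the full budget; with every
    extra constraint weight at zero the two rows coincide by construction.
    """
    budget = replace(params, max_iter=n_iter, tol=0.0)
    init = svd_init(x1, x2, params.K, params.seed)
    plain = jnmf_fit(x1, x2, budget, init=init)
    full = fit(x1, x2, d, a, b1, b2, budget, init=init)
    table = pd.DataFrame(
        {
            "reconstruction_error": [
                relative_error(x1, x2, plain.W, plain.H1, plain.H2),
                relative_error(x1, x2, full.W, full.H1, full.H2),
            ],
            "l1_norm": [_l1_norm(plain), _l1_norm(full)],
            "n_iter": [plain.n_iter, full.n_iter],
        },
        index=["jnmf", "full"],
    )
    return ComparisonReport(table, n_iter, plain, full)


_GRIDS = {
    "random_forest": {
        "clf__n_estimators": [100, 300],
        "clf__max_depth": [None, 3, 5],
    },
    "svm": {
        "clf__C": [0.1, 1.0, 10.0],
        "clf__gamma": ["scale", 0.1],
    },
    "logistic_regression": {
        "clf__C": [0.1, 1.0, 10.0],
    },
}


def _make_estimator(classifier: str, seed: int) -> Pipeline:
    if classifier == "random_forest":
        clf = RandomForestClassifier(random_state=seed)
    elif classifier == "svm":
        clf = SVC(kernel="rbf", random_state=seed)
    elif classifier == "logistic_regression":
        clf = LogisticRegression(max_iter=5000, random_state=seed)
    else:
        raise ValidationError(f"unknown classifier {classifier!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def classify_patients(
    features: np.ndarray | ModalityMatrix | pd.DataFrame,
    labels: DiagnosisVector | np.ndarray,
    classifier: Literal["random_forest", "svm", "logistic_regression"] = "random_forest",
    seed: int = 0,
    train_fraction: float = 0.75,
) -> ClassificationReport:
    """Stratified 75/25 split, small CV grid search, test-set ROC/AUC."""
    if isinstance(features, ModalityMatrix):
        X = features.values
    elif isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = labels.labels if isinstance(labels, DiagnosisVector) else np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise ValidationError("feature rows and labels disagree")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("need both diagnosis classes for classification")
    if counts.min() < 4:
        raise ValidationError("need at least 4 samples per class")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed
    )
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_estimator(classifier, seed),
        _GRIDS[classifier],
        cv=cv,
        scoring="roc_auc",
        n_jobs=1,
    )
    search.fit(X_tr, y_tr)
    model = search.best_estimator_
    if hasattr(model, "predict_proba"):
        pos = list(model.classes_).index(2)
        score = model.predict_proba(X_te)[:, pos]
    else:
        score = model.decision_function(X_te)
    fpr, tpr, _ = roc_curve(y_te, score, pos_label=2)
    return ClassificationReport(
        classifier=classifier,
        best_params={k.removeprefix("clf__"): v for k, v in search.best_params_.items()},
        seed=seed,
        fpr=fpr,
        tpr=tpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        n_train=X_tr.shape[0],
        n_test=X_te.shape[0],
    )
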