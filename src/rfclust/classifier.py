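"""Transfer of discovery-cluster labels to new cohorts via a classifier.

After clustering the discovery cohort, a supervised model is trained with
cluster membership as the dependent variable and the five risk factors
as predictors, so that participants of an independent cohort can be
assigned to the discovered clusters without re-clustering.  The default
model is an RBF-kernel support vector machine (one-vs-one multiclass)
on z-scored features, with the margin penalty and kernel width chosen by
stratified cross-validation; inverse-frequency class weights protect the
smallest cluster.  A multinomial-logistic fallback is available for
debuggability.

The feature scaler is frozen at training time: applying the model to a
validation cohort never refits scaling on that cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .gower import RISK_FACTORS
from .rfc import ClusterAssignment

DEFAULT_GRID = {"svc__C": [1.0, 10.0, 100.0], "svc__gamma": ["scale", 0.1, 1.0]}


@dataclass
class ClusterClassifier:
    """Frozen cluster-discrimination model plus training metadata."""

    pipeline: Pipeline
    classes: np.ndarray
    seed: int
    hyperparameters: Mapping
    cv_accuracy: float
    features: tuple[str, ...] = RISK_FACTORS

    def feature_matrix(self, cohort) -> np.ndarray:
        df = getattr(cohort, "df", cohort)
        missing = [c for c in self.features if c not in df.columns]
        if missing:
            raise ValueError(f"cohort lacks risk-factor columns: {missing}")
        return df[list(self.features)].to_numpy(dtype=float)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ClusterClassifier":
        return joblib.load(path)


def train_cluster_classifier(
    cohort,
    assignment: ClusterAssignment,
    seed: int = 0,
    model: str = "svm",
    param_grid: Mapping | None = None,
    cv_folds: int = 5,
) -> ClusterClassifier:
    """Fit the cluster-discrimination model on a labelled cohort.

    Parameters
    ----------
    cohort : CohortTable or DataFrame with the five risk factors.
    assignment : cluster labels aligned with the cohort rows.
    model : "svm" (default) or "logistic" for the transparent fallback.
    param_grid : hyperparameter grid for the SVM search; defaults to a
        small grid over C and gamma.
    cv_folds : stratified CV folds for both the grid search and the
        reported CV accuracy.

    Raises
    ------
    ValueError
        If any cluster has fewer members than the number of CV folds.
    """
    df = getattr(cohort, "df", cohort)
    X = df[list(RISK_FACTORS)].to_numpy(dtype=float)
    y = assignment.labels
    if len(y) != len(X):
        raise ValueError("assignment does not cover the cohort")
    if assignment.k < 2:
        raise ValueError("need at least 2 clusters to train a classifier")
    sizes = assignment.sizes()
    if sizes.min() < cv_folds:
        raise ValueError(
            f"smallest cluster ({sizes.min()} members) is below the CV fold "
            f"count ({cv_folds})"
        )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    if model == "svm":
        pipe = Pipeline(
            [
                ("scaler", StandardScaler()),
                ("svc", SVC(kernel="rbf", class_weight="balanced", random_state=seed)),
            ]
        )
        search = GridSearchCV(
            pipe, param_grid or DEFAULT_GRID, cv=cv, scoring="accuracy", n_jobs=1
        )
        search.fit(X, y)
        fitted = search.best_estimator_
        params = dict(search.best_params_)
        cv_acc = float(search.best_score_)
    elif model == "logistic":
        fitted = Pipeline(
            [
                ("scaler", StandardScaler()),
                (
                    "logit",
                    LogisticRegression(
                        max_iter=2000, class_weight="balanced", random_state=seed
                    ),
                ),
            ]
        )
        from sklearn.model_selection import cross_val_score

        cv_acc = float(np.mean(cross_val_score(fitted, X, y, cv=cv)))
        fitted.fit(X, y)
        params = {"model": "logistic"}
    else:
        raise ValueError("model must be 'svm' or 'logistic'")
    return ClusterClassifier(
        pipeline=fitted,
        classes=np.array(sorted(np.unique(y))),
        seed=seed,
        hyperparameters=params,
        cv_accuracy=cv_acc,
    )


def assign_clusters(model: ClusterClassifier, cohort) -> ClusterAssignment:
    """Label a cohort with the frozen model; never refits the scaler.

    Features outside the numeric domain seen in training raise a warning
    but are still predicted (the scaler extrapolates linearly).
    """
    X = model.feature_matrix(cohort)
    scaler: StandardScaler = model.pipeline.named_steps["scaler"]
    lo = scaler.mean_ - 4 * scaler.scale_
    hi = scaler.mean_ + 4 * scaler.scale_
    outside = (X < lo) | (X > hi)
    if outside.any():
        warnings.warn(
            f"{int(outside.any(axis=1).sum())} rows have features far outside "
            "the training domain; predictions extrapolate"
        )
    labels = model.pipeline.predict(X)
    df = getattr(cohort, "df", cohort)
    pid = df["participant_id"].to_numpy() if "participant_id" in df.columns else None
    # k stays the training k so downstream tables keep the discovery
    # layout even if a class receives no predictions
    k = int(model.classes.max())
    return ClusterAssignment(labels=labels, k=k, participant_id=pid, allow_missing=True)
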