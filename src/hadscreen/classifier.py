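"""Model family benchmarking, the gradient-boosted screen, and L1 feature relevance.

The screening protocol is built around a gradient-boosted decision-tree
ensemble whose ``max_depth`` is chosen by cross-validated grid search (ties
resolved toward the shallowest tree).  A most-frequent-class dummy predictor
anchors the benchmark; cross-validation is stratified because class balance
can be as skewed as 92:8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import Lasso, SGDClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .registry import HAD

logger = logging.getLogger(__name__)

BASELINE_FAMILY = "dummy"


def default_families(seed: int = 0) -> dict:
    """The benchmark roster: a dummy baseline plus seven standard families."""
    return {
        BASELINE_FAMILY: DummyClassifier(strategy="most_frequent"),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "sgd": SGDClassifier(random_state=seed),
        "kneighbors": KNeighborsClassifier(),
        "gaussian_process": GaussianProcessClassifier(random_state=seed),
        "gaussian_nb": GaussianNB(),
        "random_forest": RandomForestClassifier(random_state=seed),
        "gradient_boosting": GradientBoostingClassifier(random_state=seed),
    }


@dataclass
class BenchmarkReport:
    accuracies: dict  # family -> mean CV accuracy
    baseline_accuracy: float
    selected_family: str
    failed: list = field(default_factory=list)
    folds: int = 3
    seed: int = 0
    stratified: bool = True
    metric: str = "accuracy"


def benchmark(
    features: pd.DataFrame,
    labels: Sequence[str],
    families: Optional[Mapping] = None,
    folds: int = 3,
    seed: int = 0,
) -> BenchmarkReport:
    """Cross-validate every requested family and select the best mean accuracy.

    The dummy baseline never wins selection; families that fail to fit are
    recorded and excluded.  Deterministic for a given seed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if families is None:
        families = default_families(seed)
    if BASELINE_FAMILY not in families:
        families = {BASELINE_FAMILY: DummyClassifier(strategy="most_frequent"), **families}
    y = np.asarray(labels)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accuracies: dict = {}
    failed: list = []
    for name, est in families.items():
        try:
            scores = cross_val_score(clone(est), features.values, y, cv=cv, scoring="accuracy")
        except Exception as exc:  # a family failing to fit is reported, not fatal
            logger.warning("family %s failed to fit: %s", name, exc)
            failed.append(name)
            continue
        accuracies[name] = float(np.mean(scores))
    candidates = {k: v for k, v in accuracies.items() if k != BASELINE_FAMILY}
    selected = max(candidates, key=candidates.get) if candidates else BASELINE_FAMILY
    return BenchmarkReport(
        accuracies=accuracies,
        baseline_accuracy=accuracies.get(BASELINE_FAMILY, float("nan")),
        selected_family=selected,
        failed=failed,
        folds=folds,
        seed=seed,
    )


@dataclass
class ModelHandle:
    """A fitted model plus the column manifest and seed it was trained with."""

    model: object
    columns: list
    seed: int
    max_depth: int
    kind: str  # "binary" | "types"

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelHandle":
        return joblib.load(path)


def _check_columns(handle: ModelHandle, features: pd.DataFrame) -> None:
    if list(features.columns) != handle.columns:
        raise ValueError("feature columns do not match the fit-time column manifest")


def fit_binary(
    features: pd.DataFrame,
    labels: Sequence[str],
    max_depth_grid: Sequence[int] = (1, 2, 3),
    seed: int = 0,
) -> ModelHandle:
    """Fit the gradient-boosted binary screen, grid-searching ``max_depth``.

    Depth is selected by stratified cross-validated accuracy; ties break toward
    the smallest depth.  Single-class labels are fatal.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot fit a classifier")
    grid = sorted(set(int(d) for d in max_depth_grid))
    if not grid:
        raise ValueError("max_depth_grid must be non-empty")
    base = GradientBoostingClassifier(random_state=seed)
    if len(grid) == 1:
        best_depth = grid[0]
        model = clone(base).set_params(max_depth=best_depth).fit(features.values, y)
    else:
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        search = GridSearchCV(
            base, {"max_depth": grid}, scoring="accuracy", cv=cv, refit=True
        )
        # GridSearchCV keeps the first of tied scores; ascending grid => smallest depth
        search.fit(features.values, y)
        best_depth = int(search.best_params_["max_depth"])
        model = search.best_estimator_
    return ModelHandle(
        model=model, columns=list(features.columns), seed=seed,
        max_depth=best_depth, kind="binary",
    )


def fit_types(
    features: pd.DataFrame,
    labels: Sequence[str],
    max_depth_grid: Sequence[int] = (1, 2, 3),
    seed: int = 0,
) -> ModelHandle:
    """Fit one multiclass gradient-boosted model over the seven cycle-2 labels."""
    handle = fit_binary(features, labels, max_depth_grid=max_depth_grid, seed=seed)
    handle.kind = "types"
    return handle


def predict_proba(handle: ModelHandle, features: pd.DataFrame) -> pd.DataFrame:
    """Class probabilities per visit; columns are the model's classes.

    Probabilities are finite and in [0, 1]; each row sums to 1.  A feature
    frame whose columns differ from the fit-time manifest is fatal.
    """
    _check_columns(handle, features)
    probs = handle.model.predict_proba(features.values)
    if not np.all(np.isfinite(probs)):
        raise RuntimeError("non-finite probabilities from the model")
    return pd.DataFrame(probs, index=features.index, columns=handle.model.classes_)


def predict_had_probability(handle: ModelHandle, features: pd.DataFrame) -> np.ndarray:
    """Cycle-1 convenience: the probability of the HAD class as a flat array."""
    return predict_proba(handle, features)[HAD].to_numpy()


def feature_relevance(
    features: pd.DataFrame,
    labels: Sequence[str],
    penalty: float = 0.01,
    k: int = 5,
) -> list:
    """L1 (Lasso) feature relevance: the top-k positive and top-k negative coefficients.

    Features are standardized internally (constant columns pass through with a
    zero coefficient); the label is encoded 1 for the positive class.  Returns
    ``[(feature_name, signed_coefficient), ...]`` sorted positives first.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    y = np.asarray([1.0 if lab == HAD else 0.0 for lab in labels])
    X = StandardScaler().fit_transform(np.asarray(features, dtype=float))
    X = np.nan_to_num(X)  # constant columns standardize to 0/0
    lasso = Lasso(alpha=penalty)
    lasso.fit(X, y)
    coefs = list(zip(features.columns, lasso.coef_))
    positives = sorted((c for c in coefs if c[1] > 0), key=lambda c: -c[1])[:k]
    negatives = sorted((c for c in coefs if c[1] < 0), key=lambda c: c[1])[:k]
    return positives + negatives
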