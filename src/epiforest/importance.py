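"""Random-forest interpretation metrics and model evaluation.

Three competing global feature-importance metrics are provided for a fitted
random forest on a genotype/phenotype dataset:

``PFI``
    A custom permutation feature importance: per repeat the data are
    shuffled and split, the model refitted, and the *relative* decrease in
    held-out balanced accuracy after permuting each feature (or each
    feature pair/trio for PFI2/PFI3) recorded; scores are per-feature means
    over repeats, clipped at zero and normalized to sum to 1.
``BIC``
    The forest's built-in impurity-decrease (Gini) importances.
``SHAP``
    Mean absolute exact tree-Shapley attribution per feature.

Model quality is measured by stratified cross-validated balanced accuracy,
with a label-permutation test for classification significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import recall_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .datatypes import ImportanceProfile
from .errors import InvalidArgumentError, UndefinedScoreError

DEFAULT_RF_PARAMS = dict(n_estimators=100, criterion="gini", max_features="sqrt")

DEFAULT_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [None, 5, 10],
    "min_samples_leaf": [1, 5],
}


def default_forest(random_state: int | None = None, **overrides) -> RandomForestClassifier:
    """The reference classifier: a Gini random forest."""
    params = {**DEFAULT_RF_PARAMS, **overrides}
    return RandomForestClassifier(random_state=random_state, **params)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Unweighted mean of per-class recall, in [0, 1]."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InvalidArgumentError("y_true and y_pred must have equal length")
    classes = np.unique(y_true)
    if classes.size < 2:
        raise UndefinedScoreError("balanced accuracy needs both classes in y_true")
    recalls = recall_score(y_true, y_pred, labels=classes, average=None)
    return float(np.mean(recalls))


@dataclass
class FitResult:
    """A fitted forest plus its cross-validated performance."""

    model: object
    hyperparameters: dict
    cv_balanced_accuracy: float
    fold_scores: list[float]
    seed: int | None = None

    def __post_init__(self) -> None:
        for s in self.fold_scores:
            if not 0.0 <= s <= 1.0:
                raise InvalidArgumentError(f"fold score {s} outside [0, 1]")


def cv_balanced_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    model_factory: Callable[..., object] | None = None,
    rng: np.random.Generator | int | None = None,
    grid: dict | None = None,
) -> FitResult:
    """Stratified k-fold balanced accuracy plus a final fit on all data.

    With ``grid`` given, hyperparameters are first tuned by grid search
    (balanced-accuracy scoring) and the tuned settings used throughout.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = y.size
    if folds > n:
        raise InvalidArgumentError(f"folds={folds} exceeds n={n}")
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.size < 2:
        raise UndefinedScoreError("y has a single class")
    if class_counts.min() < folds:
        raise InvalidArgumentError(
            f"smallest class has {class_counts.min()} samples; cannot stratify "
            f"into {folds} folds"
        )
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31))
    factory = model_factory or default_forest

    params: dict = {}
    if grid:
        search = GridSearchCV(
            factory(random_state=seed),
            grid,
            scoring="balanced_accuracy",
            cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
        )
        search.fit(X, y)
        params = dict(search.best_params_)

    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    fold_scores = []
    for train, test in skf.split(X, y):
        model = factory(random_state=seed, **params)
        model.fit(X[train], y[train])
        fold_scores.append(balanced_accuracy(y[test], model.predict(X[test])))
    final = factory(random_state=seed, **params)
    final.fit(X, y)
    return FitResult(
        model=final,
        hyperparameters=dict(final.get_params()),
        cv_balanced_accuracy=float(np.mean(fold_scores)),
        fold_scores=fold_scores,
        seed=seed,
    )


def permutation_feature_importance(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    tuple_size: int = 1,
    n_repeats: int | None = None,
    test_size: float = 0.25,
    model_factory: Callable[..., object] | None = None,
    rng: np.random.Generator | int | None = None,
) -> ImportanceProfile:
    """Custom permutation feature importance (single- or multi-feature).

    Per repeat: stratified shuffle/split, fit on train, balanced accuracy
    BA0 on test; for each feature (or each unordered pair/trio with
    ``tuple_size`` 2/3) the test column(s) are permuted — each column of a
    tuple shuffled independently, destroying the joint signal — and the
    relative decrease (BA0 - BAp) / BA0 recorded.  Unit scores are means
    over repeats, negatives clipped to 0, then normalized to sum to 1
    (raw means are retained unclipped).  ``n_repeats`` defaults to m - 1.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n, m = X.shape
    if tuple_size not in (1, 2, 3):
        raise InvalidArgumentError("tuple_size must be 1, 2 or 3")
    if np.unique(y).size < 2:
        raise UndefinedScoreError("y has a single class")
    if n_repeats is None:
        n_repeats = max(m - 1, 1)
    if n_repeats < 1:
        raise InvalidArgumentError("n_repeats must be >= 1")
    feature_ids = list(feature_ids) if feature_ids else [f"f{j+1}" for j in range(m)]
    if len(feature_ids) != m:
        raise InvalidArgumentError("feature_ids length mismatch")
    units = (
        list(feature_ids)
        if tuple_size == 1
        else [tuple(feature_ids[j] for j in c) for c in combinations(range(m), tuple_size)]
    )
    unit_cols = (
        [(j,) for j in range(m)]
        if tuple_size == 1
        else list(combinations(range(m), tuple_size))
    )
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    factory = model_factory or default_forest

    decreases = np.zeros((n_repeats, len(units)))
    absolute_fallback = False
    for r in range(n_repeats):
        split_seed = int(rng.integers(2**31))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_size, stratify=y, random_state=split_seed
        )
        model = factory(random_state=int(rng.integers(2**31)))
        model.fit(X_tr, y_tr)
        ba0 = balanced_accuracy(y_te, model.predict(X_te))
        for u, cols in enumerate(unit_cols):
            X_perm = X_te.copy()
            for c in cols:  # independent shuffle per column of the tuple
                X_perm[:, c] = X_te[rng.permutation(X_te.shape[0]), c]
            bap = balanced_accuracy(y_te, model.predict(X_perm))
            if ba0 > 0:
                decreases[r, u] = (ba0 - bap) / ba0
            else:
                decreases[r, u] = ba0 - bap
                absolute_fallback = True
    raw = decreases.mean(axis=0)
    metric = {1: "PFI", 2: "PFI2", 3: "PFI3"}[tuple_size]
    prof = ImportanceProfile.from_raw(
        metric,
        units,
        raw,
        model_descriptor=type(factory(random_state=0)).__name__,
        seed=seed,
        metadata={
            "n_repeats": n_repeats,
            "test_size": test_size,
            "absolute_fallback": absolute_fallback,
        },
    )
    return prof


def builtin_gini_importance(
    fit: FitResult, feature_ids: Sequence[str] | None = None
) -> ImportanceProfile:
    """The forest's impurity-decrease importances, normalized to sum 1."""
    model = fit.model if isinstance(fit, FitResult) else fit
    try:
        raw = np.asarray(model.feature_importances_, dtype=float)
    except AttributeError as exc:
        raise InvalidArgumentError("model is not fitted or lacks importances") from exc
    ids = list(feature_ids) if feature_ids else [f"f{j+1}" for j in range(raw.size)]
    return ImportanceProfile.from_raw(
        "BIC", ids, raw, model_descriptor=type(model).__name__
    )


def shap_mean_importance(
    fit: FitResult,
    X: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    absolute: bool = True,
) -> ImportanceProfile:
    """Global mean-SHAP importance from exact tree-Shapley attributions.

    The per-feature score is the mean of absolute per-sample attributions
    (the standard global SHAP summary); ``absolute=False`` averages signed
    values instead.
    """
    from .shapley import tree_shap_values

    model = fit.model if isinstance(fit, FitResult) else fit
    X = np.asarray(X, dtype=np.float64)
    if X.size == 0:
        raise InvalidArgumentError("X is empty")
    phi = tree_shap_values(model, X)
    raw = np.abs(phi).mean(axis=0) if absolute else phi.mean(axis=0)
    ids = list(feature_ids) if feature_ids else [f"f{j+1}" for j in range(X.shape[1])]
    return ImportanceProfile.from_raw(
        "SHAP", ids, raw, model_descriptor=type(model).__name__,
        metadata={"absolute": absolute},
    )


def label_permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 99,
    folds: int = 10,
    model_factory: Callable[..., object] | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, np.ndarray, float]:
    """Permutation test of classifier significance.

    Observed cross-validated balanced accuracy is compared against B
    re-computations on label-permuted data; the empirical p-value is
    (1 + #{null >= observed}) / (B + 1).
    """
    if B < 19:
        raise InvalidArgumentError("B must be >= 19 for a meaningful p-value")
    rng = np.random.default_rng(rng)
    observed = cv_balanced_accuracy(
        X, y, folds=folds, model_factory=model_factory, rng=rng
    ).cv_balanced_accuracy
    nulls = np.empty(B)
    for b in range(B):
        y_perm = np.asarray(y)[rng.permutation(len(y))]
        nulls[b] = cv_balanced_accuracy(
            X, y_perm, folds=folds, model_factory=model_factory, rng=rng
        ).cv_balanced_accuracy
    p = (1 + int((nulls >= observed).sum())) / (B + 1)
    return observed, nulls, p
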