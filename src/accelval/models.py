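"""Nested cross-validated training, evaluation and importance analysis.

Evaluation protocol
-------------------
Data are split over feature windows (not participants) into 5 outer
folds. In each fold 20% is held-out test data and 80% development data;
the development data is further split 80/20 into training and validation.
Collinear-feature removal and hyper-parameter selection see only the
development data (candidates are fit on training and scored on
validation); the winning setting is refit on all development data and
measured once on the untouched test fold. Pooled metrics aggregate the
five folds' test predictions.

Metrics follow the wearable-validation conventions: micro-averaged
(overall) accuracy, per-class balanced accuracy (mean of one-vs-rest
sensitivity and specificity), and column-normalized confusion matrices
(rows = predicted, columns = actual, each column divided by its true
count). Random-forest feature importance is the total mean decrease in
Gini impurity (classification) or in node residual sum of squares
(regression), summed over all trees.

The learners themselves are scikit-learn estimators; this module owns the
splitting, tuning protocol, metrics and importance aggregation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .errors import ConfigError, UndefinedStatisticError

MODEL_KINDS = ("decision_tree", "random_forest", "svm", "neural_net")

DEFAULT_COLLINEARITY_THRESHOLD = 0.9
DEFAULT_FOREST_SIZE = 500


@dataclass(frozen=True)
class Fold:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    @property
    def development(self) -> np.ndarray:
        return np.concatenate([self.train, self.validation])


@dataclass(frozen=True)
class SplitPlan:
    """Outer-fold index sets for nested cross-validation."""

    n_items: int
    outer_folds: int
    folds: tuple[Fold, ...]
    seed: int

    def __post_init__(self):
        covered = np.concatenate([f.test for f in self.folds])
        if len(np.unique(covered)) != len(covered) or len(covered) != self.n_items:
            raise ConfigError("outer test sets must be disjoint and cover all items")
        for f in self.folds:
            alls = np.concatenate([f.train, f.validation, f.test])
            if len(np.unique(alls)) != self.n_items:
                raise ConfigError("each fold must partition all items")


def nested_split(
    n: int,
    outer_folds: int = 5,
    seed: int = 0,
    labels=None,
    max_retries: int = 10,
) -> SplitPlan:
    """Build the nested train/validation/test split plan.

    With ``labels`` the outer folds are stratified by class, and folds are
    re-drawn up to ``max_retries`` times if a class goes missing from any
    training set; without labels plain shuffled folds are used.
    """
    if n < outer_folds * 5:
        raise ValueError(f"need n >= {outer_folds * 5} items, got {n}")
    labels = None if labels is None else np.asarray(labels)
    for attempt in range(max_retries):
        rs = seed + attempt
        if labels is not None:
            splitter = StratifiedKFold(outer_folds, shuffle=True, random_state=rs)
            split_iter = splitter.split(np.zeros(n), labels)
        else:
            splitter = KFold(outer_folds, shuffle=True, random_state=rs)
            split_iter = splitter.split(np.zeros(n))
        folds = []
        ok = True
        for k, (dev, test) in enumerate(split_iter):
            strat = labels[dev] if labels is not None else None
            try:
                train, val = train_test_split(
                    dev, test_size=0.2, random_state=rs + 1000 + k, stratify=strat
                )
            except ValueError:  # a class too rare to stratify the inner split
                ok = False
                break
            if labels is not None and set(labels[train]) != set(labels):
                ok = False
                break
            folds.append(Fold(np.sort(train), np.sort(val), np.sort(test)))
        if ok:
            return SplitPlan(n_items=n, outer_folds=outer_folds, folds=tuple(folds), seed=seed)
    raise ValueError(
        f"could not stratify {outer_folds} folds in {max_retries} attempts; "
        "a class is too rare"
    )


def remove_collinear(
    features: pd.DataFrame, threshold: float = DEFAULT_COLLINEARITY_THRESHOLD
) -> list[str]:
    """Greedy collinear-feature filter on training data.

    While any retained pair has |Pearson r| > threshold, drop the feature
    with the highest mean absolute correlation to the others (ties break
    toward keeping the alphabetically earlier name). Returns the retained
    feature names in their original column order.
    """
    if features.shape[1] < 2:
        raise ValueError("need >= 2 features")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    corr = features.corr().abs().fillna(0.0)
    np.fill_diagonal(corr.values, 0.0)
    retained = list(features.columns)
    while True:
        sub = corr.loc[retained, retained]
        if sub.values.max() <= threshold:
            break
        mean_abs = sub.mean(axis=1)
        worst = max(retained, key=lambda name: (mean_abs[name], name))
        retained.remove(worst)
    return [c for c in features.columns if c in retained]


def confusion_matrix(
    y_true, y_pred, labels=None, normalize: bool = True
) -> pd.DataFrame:
    """Confusion matrix with rows = predicted, columns = actual.

    With ``normalize`` each column is divided by its true-class count
    (columns of classes with >= 1 true instance sum to 1); columns with no
    true instances are left as zeros.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    labels = list(labels)
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for t, p in zip(y_true, y_pred):
        counts[index[p], index[t]] += 1
    if normalize:
        col = counts.sum(axis=0)
        counts = counts / np.where(col > 0, col, 1.0)
    return pd.DataFrame(counts, index=labels, columns=labels)


def balanced_accuracy(confusion_counts: pd.DataFrame, cls) -> float:
    """One-vs-rest mean of sensitivity and specificity for one class.

    ``confusion_counts`` is an *unnormalized* confusion matrix in the
    rows-predicted / columns-actual orientation.
    """
    m = confusion_counts.to_numpy(dtype=float)
    labels = list(confusion_counts.columns)
    if cls not in labels:
        raise UndefinedStatisticError(f"class {cls!r} absent from the matrix")
    i = labels.index(cls)
    total = m.sum()
    tp = m[i, i]
    fn = m[:, i].sum() - tp
    fp = m[i, :].sum() - tp
    tn = total - tp - fn - fp
    if tp + fn == 0:
        raise UndefinedStatisticError(f"class {cls!r} has no true instances")
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    return float((sensitivity + specificity) / 2)


def gini_impurity(proportions) -> float:
    """Gini impurity 1 − Σ pᵢ² of a class-proportion vector."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("proportions must be non-negative and sum to 1")
    return float(1.0 - np.sum(p**2))


def feature_importance(forest, feature_names) -> list[tuple[str, float]]:
    """Features ranked by the forest's total mean decrease in impurity.

    For classification forests the impurity is Gini; for regression
    forests it is node residual sum of squares. Ties break alphabetically.
    """
    if not isinstance(forest, (RandomForestClassifier, RandomForestRegressor)):
        raise TypeError("importance ranking requires a fitted random forest")
    importances = forest.feature_importances_
    order = sorted(zip(feature_names, importances), key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(v)) for name, v in order]


@dataclass
class RegressionResult:
    """METs-regression evaluation: RMSE (MET units) and r²."""

    model_kind: str
    rmse: float
    r_squared: float
    per_fold_rmse: list[float] = field(default_factory=list)
    importance: list[tuple[str, float]] | None = None
    retained_features: list[list[str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if self.r_squared > 1:
            raise ValueError("r_squared cannot exceed 1")


def evaluate_regression(predictions, truths, model_kind: str = "") -> RegressionResult:
    """RMSE and coefficient of determination r² = 1 − SSE/SST."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if len(p) != len(t) or len(t) < 2:
        raise ValueError("need equal-length sequences of >= 2 values")
    sse = float(np.sum((t - p) ** 2))
    sst = float(np.sum((t - t.mean()) ** 2))
    if sst == 0:
        raise UndefinedStatisticError("r² undefined: truths have zero variance")
    return RegressionResult(
        model_kind=model_kind,
        rmse=float(np.sqrt(np.mean((t - p) ** 2))),
        r_squared=1.0 - sse / sst,
    )


@dataclass
class ModelResult:
    """Per-task classification evaluation under the nested-CV protocol."""

    model_kind: str
    task: str
    labels: list
    overall_accuracy: float  # pooled micro-averaged fraction correct
    fold_accuracies: list[float]
    confusion_counts: pd.DataFrame  # pooled, rows=predicted, cols=actual
    confusion: pd.DataFrame  # column-normalized
    per_class_balanced_accuracy: dict
    importance: list[tuple[str, float]] | None
    retained_features: list[list[str]]
    plan: SplitPlan
    seed: int
    chosen_params: list[dict]
    stage_fingerprints: list[dict]
    pooled_true: np.ndarray = field(repr=False, default=None)
    pooled_pred: np.ndarray = field(repr=False, default=None)

    @property
    def fold_mean_accuracy(self) -> float:
        """Mean of per-fold accuracies (the pooled value is primary)."""
        return float(np.mean(self.fold_accuracies))


# Hyper-parameter candidate grids, ordered simplest -> most complex so that
# validation-accuracy ties resolve to the simpler setting. The study these
# defaults emulate specifies none, beyond 500 trees for the forest.
_CLS_GRIDS = {
    "decision_tree": [{"max_depth": d} for d in (3, 5, None)],
    "random_forest": [{"n_estimators": DEFAULT_FOREST_SIZE, "max_features": "sqrt"}],
    "svm": [{"C": c} for c in (1.0, 10.0)],
    "neural_net": [{"hidden_layer_sizes": h} for h in ((16,), (64,))],
}


def _make_classifier(kind: str, params: dict, seed: int):
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if kind == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", gamma="scale", **params))
    if kind == "neural_net":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(random_state=seed, max_iter=600, **params),
        )
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def _make_regressor(kind: str, params: dict, seed: int):
    if kind == "decision_tree":
        return DecisionTreeRegressor(random_state=seed, **params)
    if kind == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if kind == "svm":
        return make_pipeline(StandardScaler(), SVR(kernel="rbf", gamma="scale", **params))
    if kind == "neural_net":
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(random_state=seed, max_iter=800, **params),
        )
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def _fingerprint(X: pd.DataFrame, idx: np.ndarray) -> str:
    """Digest of the exact rows a protocol stage received."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X.to_numpy()[np.sort(idx)]).tobytes())
    return h.hexdigest()


def _extract_forest(model):
    if isinstance(model, (RandomForestClassifier, RandomForestRegressor)):
        return model
    return None


def train_and_evaluate(
    X: pd.DataFrame,
    y,
    model_kind: str,
    plan: SplitPlan,
    seed: int = 0,
    task: str = "",
    grids: dict | None = None,
    collinearity_threshold: float = DEFAULT_COLLINEARITY_THRESHOLD,
) -> ModelResult:
    """Run the full nested-CV protocol for one classifier family.

    Per outer fold: collinear features are removed using development data
    only; each hyper-parameter candidate is fit on training and scored by
    validation overall accuracy (first — i.e. simplest — candidate wins
    ties); the winner is refit on all development data and evaluated on
    the untouched test fold. Pooled metrics aggregate fold test
    predictions. Deterministic given (data, plan, seed).
    """
    y = np.asarray(y)
    if len(X) != plan.n_items or len(y) != plan.n_items:
        raise ValueError("dataset rows must align with the split plan")
    if len(set(y)) < 2:
        raise ValueError("need >= 2 classes")
    grid = (grids or _CLS_GRIDS)[model_kind]
    labels = sorted(set(y))

    pooled_true, pooled_pred = [], []
    fold_accuracies, retained_all, chosen_params = [], [], []
    fingerprints = []
    importances = []
    for k, fold in enumerate(plan.folds):
        dev = fold.development
        retained = remove_collinear(X.iloc[dev], collinearity_threshold)
        Xr = X[retained]
        best_params, best_score = None, -np.inf
        for params in grid:
            model = _make_classifier(model_kind, params, seed + k)
            model.fit(Xr.iloc[fold.train], y[fold.train])
            score = float(np.mean(model.predict(Xr.iloc[fold.validation]) == y[fold.validation]))
            if score > best_score:  # strict: ties keep the earlier/simpler candidate
                best_score, best_params = score, params
        final = _make_classifier(model_kind, best_params, seed + k)
        final.fit(Xr.iloc[dev], y[dev])
        pred = final.predict(Xr.iloc[fold.test])
        pooled_true.append(y[fold.test])
        pooled_pred.append(pred)
        fold_accuracies.append(float(np.mean(pred == y[fold.test])))
        retained_all.append(retained)
        chosen_params.append(best_params)
        fingerprints.append(
            {
                "collinearity_rows": _fingerprint(X, dev),
                "tuning_fit_rows": _fingerprint(X, fold.train),
                "tuning_score_rows": _fingerprint(X, fold.validation),
                "final_fit_rows": _fingerprint(X, dev),
                "test_rows": _fingerprint(X, fold.test),
            }
        )
        forest = _extract_forest(final)
        if forest is not None:
            importances.append(dict(feature_importance(forest, retained)))

    y_true = np.concatenate(pooled_true)
    y_pred = np.concatenate(pooled_pred)
    counts = confusion_matrix(y_true, y_pred, labels=labels, normalize=False)
    normalized = confusion_matrix(y_true, y_pred, labels=labels, normalize=True)
    per_class = {c: balanced_accuracy(counts, c) for c in labels}

    importance = None
    if importances:
        merged: dict[str, float] = {}
        for imp in importances:
            for name, v in imp.items():
                merged[name] = merged.get(name, 0.0) + v / len(importances)
        importance = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))

    return ModelResult(
        model_kind=model_kind,
        task=task,
        labels=labels,
        overall_accuracy=float(np.mean(y_true == y_pred)),
        fold_accuracies=fold_accuracies,
        confusion_counts=counts,
        confusion=normalized,
        per_class_balanced_accuracy=per_class,
        importance=importance,
        retained_features=retained_all,
        plan=plan,
        seed=seed,
        chosen_params=chosen_params,
        stage_fingerprints=fingerprints,
        pooled_true=y_true,
        pooled_pred=y_pred,
    )


_REG_GRIDS = {
    "decision_tree": [{"max_depth": d} for d in (3, 5, None)],
    "random_forest": [{"n_estimators": DEFAULT_FOREST_SIZE, "max_features": 1.0 / 3}],
    "svm": [{"C": c} for c in (1.0, 10.0)],
    "neural_net": [{"hidden_layer_sizes": h} for h in ((16,), (64,))],
}


def train_and_evaluate_regression(
    X: pd.DataFrame,
    y,
    model_kind: str,
    plan: SplitPlan,
    seed: int = 0,
    grids: dict | None = None,
    collinearity_threshold: float = DEFAULT_COLLINEARITY_THRESHOLD,
) -> RegressionResult:
    """Nested-CV METs regression; candidates are scored by validation RMSE."""
    y = np.asarray(y, dtype=float)
    if len(X) != plan.n_items or len(y) != plan.n_items:
        raise ValueError("dataset rows must align with the split plan")
    grid = (grids or _REG_GRIDS)[model_kind]
    pooled_pred, pooled_true = [], []
    per_fold_rmse, retained_all = [], []
    importances = []
    for k, fold in enumerate(plan.folds):
        dev = fold.development
        retained = remove_collinear(X.iloc[dev], collinearity_threshold)
        Xr = X[retained]
        best_params, best_rmse = None, np.inf
        for params in grid:
            model = _make_regressor(model_kind, params, seed + k)
            model.fit(Xr.iloc[fold.train], y[fold.train])
            resid = model.predict(Xr.iloc[fold.validation]) - y[fold.validation]
            rmse = float(np.sqrt(np.mean(resid**2)))
            if rmse < best_rmse:
                best_rmse, best_params = rmse, params
        final = _make_regressor(model_kind, best_params, seed + k)
        final.fit(Xr.iloc[dev], y[dev])
        pred = final.predict(Xr.iloc[fold.test])
        pooled_pred.append(pred)
        pooled_true.append(y[fold.test])
        per_fold_rmse.append(float(np.sqrt(np.mean((pred - y[fold.test]) ** 2))))
        retained_all.append(retained)
        forest = _extract_forest(final)
        if forest is not None:
            importances.append(dict(feature_importance(forest, retained)))
    result = evaluate_regression(
        np.concatenate(pooled_pred), np.concatenate(pooled_true), model_kind=model_kind
    )
    result.per_fold_rmse = per_fold_rmse
    result.retained_features = retained_all
    result.seed = seed
    if importances:
        merged: dict[str, float] = {}
        for imp in importances:
            for name, v in imp.items():
                merged[name] = merged.get(name, 0.0) + v / len(importances)
        result.importance = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    return result
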