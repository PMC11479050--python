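"""Four-way tone classification: split, cross-validated tuning, metrics,
confusion matrices and permutation feature importance.

Protocol: the labeled feature table is split 80:20 (stratified by class;
optionally grouped by subject so no subject straddles the split), each of
the four model families (KNN, SVM, RF, GBM) is tuned by grid search
maximizing mean 10-fold cross-validated accuracy on the training portion,
and the refit winner is scored on the held-out test portion with
macro-averaged accuracy/precision/recall/F1 plus a row-percentage confusion
matrix.  Feature importance is permutation importance on the test set,
floored at zero and normalized to percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES, TABLE_COLUMNS
from .synth import MUSCLES

MODEL_KINDS = ("knn", "svm", "rf", "gbm")

#: Class order used for every confusion matrix and per-class metric.
CLASS_ORDER = ("spastic", "rigid", "hypotonic", "normal")

FEATURE_COLUMNS = [c for c in TABLE_COLUMNS if c != "label"]

#: Default hyperparameter grids (estimator step is named "model").
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {
        "model__n_neighbors": [1, 3, 5, 7, 9, 11, 13, 15],
        "model__weights": ["uniform", "distance"],
    },
    "svm": {
        "model__C": [0.1, 1.0, 10.0, 100.0],
        "model__gamma": ["scale", 0.01, 0.1, 1.0],
    },
    "rf": {
        "model__n_estimators": [200, 500],
        "model__max_depth": [None, 10],
        "model__max_features": ["sqrt", 0.5],
    },
    "gbm": {
        "model__learning_rate": [0.05, 0.1],
        "model__max_depth": [2, 3],
        "model__n_estimators": [100],
    },
}


class SplitSpec(BaseModel):
    """Train/test split and cross-validation protocol parameters."""

    train_fraction: float = 0.8
    cv_folds: int = 10
    stratified: bool = True
    grouping: str = "sample"  # or "subject"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SplitSpec":
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.grouping not in ("sample", "subject"):
            raise ValueError("grouping must be 'sample' or 'subject'")
        return self


@dataclass
class ModelResult:
    """One model family's tuned fit and held-out evaluation."""

    kind: str
    estimator: object
    best_params: dict
    cv_accuracy: float
    accuracy: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    f1: float = float("nan")
    confusion_counts: np.ndarray | None = None
    confusion_percent: np.ndarray | None = None
    per_class: dict = field(default_factory=dict)


@dataclass
class EvalReport:
    """Full study report: all models plus importance aggregations."""

    models: dict[str, ModelResult]
    ranking: list[str]
    best_model: str
    importance_columns: dict[str, float]     # per feature column, sums to 100
    importance_features: dict[str, float]    # biceps+triceps sums, 11 entries
    importance_muscles: dict[str, float]     # per-muscle sums, 2 entries
    class_order: tuple[str, ...] = CLASS_ORDER

    def to_dict(self) -> dict:
        out: dict = {"class_order": list(self.class_order), "models": {}}
        for kind, r in self.models.items():
            out["models"][kind] = {
                "best_params": r.best_params,
                "cv_accuracy": r.cv_accuracy,
                "accuracy": r.accuracy,
                "precision": r.precision,
                "recall": r.recall,
                "f1": r.f1,
                "confusion_counts": (
                    r.confusion_counts.tolist() if r.confusion_counts is not None else None
                ),
                "confusion_percent": (
                    r.confusion_percent.tolist() if r.confusion_percent is not None else None
                ),
                "per_class": r.per_class,
            }
        out["ranking"] = self.ranking
        out["best_model"] = self.best_model
        out["importance"] = {
            "columns": self.importance_columns,
            "features": self.importance_features,
            "muscles": self.importance_muscles,
        }
        return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 80:20 split: per class, round(train_fraction * n) rows to
    train, the remainder to test.  With subject grouping, whole subjects are
    assigned per class instead of rows, so no subject straddles the split."""
    rng = np.random.default_rng(spec.seed)
    labels = table["label"].to_numpy()
    classes = [c for c in CLASS_ORDER if c in set(labels)] + sorted(
        set(labels) - set(CLASS_ORDER)
    )
    if len(set(labels)) < 2:
        raise ValueError("stratified splitting needs at least 2 classes")
    train_pos: list[np.ndarray] = []
    test_pos: list[np.ndarray] = []
    for cls in classes:
        pos = np.flatnonzero(labels == cls)
        if pos.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 rows")
        if spec.grouping == "subject":
            subjects = np.asarray(table.index)[pos]
            uniq = pd.unique(subjects)
            if uniq.size < 2:
                raise ValueError(
                    f"class {cls!r} has fewer than 2 subjects; cannot group-split"
                )
            perm = rng.permutation(uniq.size)
            n_train = int(round(spec.train_fraction * uniq.size))
            n_train = min(max(n_train, 1), uniq.size - 1)
            chosen = set(uniq[perm[:n_train]])
            is_train = np.isin(subjects, list(chosen))
            train_pos.append(pos[is_train])
            test_pos.append(pos[~is_train])
        else:
            perm = rng.permutation(pos.size)
            n_train = int(round(spec.train_fraction * pos.size))
            n_train = min(max(n_train, 1), pos.size - 1)
            train_pos.append(pos[perm[:n_train]])
            test_pos.append(pos[perm[n_train:]])
    tr = np.sort(np.concatenate(train_pos))
    te = np.sort(np.concatenate(test_pos))
    train, test = table.iloc[tr], table.iloc[te]
    for side, name in ((train, "train"), (test, "test")):
        if set(side["label"]) != set(labels):
            raise ValueError(f"a class is absent from the {name} set after splitting")
    return train, test


# ---------------------------------------------------------------------------
# model construction and tuning
# ---------------------------------------------------------------------------

def _make_pipeline(kind: str, seed: int) -> Pipeline:
    """KNN/SVM get a train-fit z-score scaler; tree ensembles take raw features."""
    if kind == "knn":
        steps = [("scale", StandardScaler()), ("model", KNeighborsClassifier())]
    elif kind == "svm":
        steps = [("scale", StandardScaler()), ("model", SVC(kernel="rbf", random_state=seed))]
    elif kind == "rf":
        steps = [("model", RandomForestClassifier(random_state=seed))]
    elif kind == "gbm":
        steps = [("model", GradientBoostingClassifier(random_state=seed))]
    else:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    return Pipeline(steps)


def train_model(
    kind: str,
    train: pd.DataFrame,
    spec: SplitSpec,
    grid: dict[str, list] | None = None,
) -> ModelResult:
    """Grid search over ``grid`` maximizing mean ``cv_folds``-fold CV accuracy
    on the training table; ties resolve to the first grid entry.  Returns the
    refit winner with its CV score."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    grid = grid if grid is not None else DEFAULT_GRIDS[kind]
    X = train[FEATURE_COLUMNS].to_numpy()
    y = train["label"].to_numpy()
    n_min = min(np.bincount(pd.factorize(y)[0]))
    folds = min(spec.cv_folds, n_min)
    if folds < 2:
        raise ValueError("too few rows per class for cross-validation")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        _make_pipeline(kind, spec.seed),
        param_grid=grid,
        scoring="accuracy",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(X, y)
    return ModelResult(
        kind=kind,
        estimator=search.best_estimator_,
        best_params={k.removeprefix("model__"): v for k, v in search.best_params_.items()},
        cv_accuracy=float(search.best_score_),
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def confusion_percentages(counts: np.ndarray) -> np.ndarray:
    """Row-normalize a confusion-count matrix to percentages (rows sum to 100)."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("a true class has no test rows")
    return 100.0 * counts / sums


def evaluate_model(result: ModelResult, test: pd.DataFrame) -> ModelResult:
    """Score a fitted model on the held-out table (macro-averaged metrics).

    Per-class precision/recall/F1 come from the confusion counts; F1 is the
    harmonic mean of precision and recall per class before macro-averaging.
    """
    labels_present = set(test["label"])
    missing = set(CLASS_ORDER) - labels_present
    if missing:
        raise ValueError(f"test set missing class(es): {sorted(missing)}")
    X = test[FEATURE_COLUMNS].to_numpy()
    y = test["label"].to_numpy()
    pred = result.estimator.predict(X)
    counts = sk_confusion(y, pred, labels=list(CLASS_ORDER))
    diag = np.diag(counts).astype(float)
    row = counts.sum(axis=1).astype(float)
    col = counts.sum(axis=0).astype(float)
    recall_c = diag / row
    precision_c = np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)
    with np.errstate(invalid="ignore"):
        f1_c = np.where(
            precision_c + recall_c > 0,
            2 * precision_c * recall_c / (precision_c + recall_c),
            0.0,
        )
    result.accuracy = float(diag.sum() / counts.sum())
    result.precision = float(precision_c.mean())
    result.recall = float(recall_c.mean())
    result.f1 = float(f1_c.mean())
    result.confusion_counts = counts
    result.confusion_percent = confusion_percentages(counts)
    result.per_class = {
        cls: {
            "precision": float(precision_c[i]),
            "recall": float(recall_c[i]),
            "f1": float(f1_c[i]),
        }
        for i, cls in enumerate(CLASS_ORDER)
    }
    return result


# ---------------------------------------------------------------------------
# importance
# ---------------------------------------------------------------------------

def feature_importance(
    result: ModelResult,
    test: pd.DataFrame,
    n_permutations: int = 20,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Permutation importance on the held-out table, as percentages.

    Per column: mean accuracy drop over ``n_permutations`` shuffles, floored
    at 0 and normalized to sum to 100.  Aggregations: per feature (biceps +
    triceps columns summed, 11 entries) and per muscle (11 columns summed,
    2 entries); each aggregation also sums to 100.
    """
    import warnings as _warnings

    X = test[FEATURE_COLUMNS].to_numpy()
    y = test["label"].to_numpy()
    res = permutation_importance(
        result.estimator, X, y,
        scoring="accuracy", n_repeats=n_permutations, random_state=seed, n_jobs=1,
    )
    raw = np.maximum(res.importances_mean, 0.0)
    total = raw.sum()
    if total <= 0:
        _warnings.warn(
            "zero total permutation importance; attributing uniformly",
            RuntimeWarning,
            stacklevel=2,
        )
        raw = np.ones_like(raw)
        total = raw.sum()
    pct = 100.0 * raw / total
    columns = dict(zip(FEATURE_COLUMNS, map(float, pct)))
    features = {
        feat: columns[f"biceps_{feat}"] + columns[f"triceps_{feat}"]
        for feat in FEATURE_NAMES
    }
    muscles = {
        muscle: float(sum(columns[f"{muscle}_{feat}"] for feat in FEATURE_NAMES))
        for muscle in MUSCLES
    }
    return columns, features, muscles


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------

def run_study(
    table: pd.DataFrame,
    spec: SplitSpec | None = None,
    grids: dict[str, dict] | None = None,
    kinds: tuple[str, ...] = MODEL_KINDS,
    n_permutations: int = 20,
) -> EvalReport:
    """End-to-end protocol: split, tune all model families, evaluate each on
    the held-out set, rank by test accuracy and attribute importance for the
    best model.  Deterministic given ``spec.seed``."""
    spec = spec or SplitSpec()
    grids = grids or {}
    train, test = split_dataset(table, spec)
    models: dict[str, ModelResult] = {}
    for kind in kinds:
        r = train_model(kind, train, spec, grids.get(kind))
        models[kind] = evaluate_model(r, test)
    ranking = sorted(models, key=lambda k: models[k].accuracy, reverse=True)
    best = ranking[0]
    cols, feats, muscles = feature_importance(
        models[best], test, n_permutations=n_permutations, seed=spec.seed
    )
    return EvalReport(
        models=models,
        ranking=ranking,
        best_model=best,
        importance_columns=cols,
        importance_features=feats,
        importance_muscles=muscles,
    )
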