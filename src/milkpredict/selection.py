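"""Cross-validated model selection, metrics, baselines, experiments.

Evaluation follows a repeated stratified k-fold protocol (default 5 folds
x 10 repetitions). Feature normalization is fitted on each training fold
and applied to its test fold, so no test information leaks into the
scaling (a ``normalize_on_all`` switch reproduces the all-data variant).
Metrics are accuracy, precision, recall and F-measure with "value >=
threshold" fixed as the positive class; they are aggregated either
macro (per-fold metrics averaged) or pooled (one confusion matrix over
all test predictions).

Hyperparameters (C, sigma) of the LSSVM are tuned by the sparrow search
algorithm in log10 space, with the swarm fitness being the mean
misclassification rate of an inner stratified k-fold at the candidate
pair.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .lssvm import LSSVMModel, train_lssvm
from .records import BinaryLabels, FeatureMatrix, apply_normalization, normalize_features
from .ssa import OptimizationResult, SSAConfig, ssa_minimize

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "f_measure",
    "make_folds",
    "fold_hash",
    "repeated_kfold",
    "default_ssa_config",
    "fit_ssa_lssvm",
    "compare_baselines",
    "feature_subset_experiment",
    "export_parallel_coordinates",
    "BASELINE_MODELS",
    "lssvm_factory",
    "sklearn_factory",
]

#: SSA search box for (log10 C, log10 sigma)
DEFAULT_LOG10_BOUNDS = ((-2.0, 4.0), (-2.0, 2.0))


@dataclass
class CVConfig:
    """Repeated stratified k-fold settings."""

    k: int = 5
    repetitions: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts partitioning the evaluated sample."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Metrics aggregated over folds x repetitions.

    ``accuracy`` .. ``f_measure`` are the macro aggregates (per-fold
    metrics averaged); ``pooled`` holds the same four metrics computed
    from one confusion matrix over all test predictions.
    """

    model_name: str
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    per_fold: pd.DataFrame = field(repr=False)
    pooled: dict[str, float] = field(default_factory=dict, repr=False)
    aggregation: str = "macro"


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN with +1 the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when P+R = 0 by convention."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F-measure from one confusion matrix.

    Zero-denominator conventions: precision and recall are 0 when their
    denominators vanish, as is F when precision + recall = 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure(precision, recall),
    }


def _derived_seed(seed: int, stream: int) -> int:
    """Stable sub-seed below 2^31 for repetition ``stream``."""
    return int(
        np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31 - 1)
    )


def make_folds(
    y: np.ndarray, cv: CVConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index pairs for all repetitions (k * repetitions pairs).

    Stratified folds keep per-fold class proportions within one sample of
    the global proportion; each repetition reshuffles with a seed derived
    from ``cv.seed``.
    """
    y = np.asarray(y)
    n = y.size
    if n < cv.k:
        raise ValueError("fewer samples than folds")
    classes, counts = np.unique(y, return_counts=True)
    if cv.stratified and classes.size == 2 and counts.min() < cv.k:
        raise ValueError(
            "minority class smaller than k: stratified folds would leave "
            "single-class training partitions"
        )
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(cv.repetitions):
        seed = _derived_seed(cv.seed, rep)
        splitter = (
            StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=seed)
            if cv.stratified
            else KFold(n_splits=cv.k, shuffle=True, random_state=seed)
        )
        for train_idx, test_idx in splitter.split(np.zeros(n), y):
            if np.unique(y[train_idx]).size < 2:
                raise ValueError("a training fold contains a single class")
            folds.append((train_idx, test_idx))
    return folds


def fold_hash(folds: Sequence[tuple[np.ndarray, np.ndarray]]) -> str:
    """Digest of the fold assignment, for paired-comparison audits."""
    h = hashlib.sha256()
    for train_idx, test_idx in folds:
        h.update(np.asarray(train_idx, dtype=np.int64).tobytes())
        h.update(b"|")
        h.update(np.asarray(test_idx, dtype=np.int64).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# model factories: callable(X_train, y_train) -> object with .predict(X_test)


def lssvm_factory(C: float = 1.0, sigma: float = 1.0) -> Callable:
    def factory(X: np.ndarray, y: np.ndarray) -> LSSVMModel:
        return train_lssvm(X, y, C=C, sigma=sigma)

    return factory


class _SKWrapper:
    def __init__(self, est):
        self._est = est

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self._est.predict(X), dtype=int)


def sklearn_factory(estimator_builder: Callable[[int], object]) -> Callable:
    """Wrap a scikit-learn estimator builder (given a seed) as a factory."""

    def factory(X: np.ndarray, y: np.ndarray, seed: int = 0):
        est = estimator_builder(seed)
        est.fit(X, y)
        return _SKWrapper(est)

    return factory


#: stock comparator learners (the bespoke models are LSSVM and SSA-LSSVM)
BASELINE_MODELS: Mapping[str, Callable[[int], object]] = {
    "KNN": lambda seed: KNeighborsClassifier(),
    "NaiveBayes": lambda seed: GaussianNB(),
    "DecisionTree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "LDA": lambda seed: LinearDiscriminantAnalysis(),
}


def _as_array(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def _as_labels(y) -> np.ndarray:
    return y.values if isinstance(y, BinaryLabels) else np.asarray(y, dtype=int)


def repeated_kfold(
    X: FeatureMatrix | np.ndarray,
    y: BinaryLabels | np.ndarray,
    model_factory: Callable,
    cv: CVConfig | None = None,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    normalize: bool = True,
    normalize_on_all: bool = False,
    model_name: str = "model",
) -> MetricsReport:
    """Evaluate a training procedure under repeated stratified k-fold.

    ``model_factory(X_train, y_train)`` must return an object with a
    ``predict(X_test)`` method. Precomputed ``folds`` override ``cv`` fold
    generation (for paired comparisons across models).
    """
    cv = cv or CVConfig()
    Xv = _as_array(X)
    yv = _as_labels(y)
    if folds is None:
        folds = make_folds(yv, cv)
    if normalize_on_all:
        col_means = Xv.mean(axis=0)
        if not (col_means > 0).all():
            raise ValueError("column mean not strictly positive")
    rows = []
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        X_train, X_test = Xv[train_idx], Xv[test_idx]
        if normalize:
            means = col_means if normalize_on_all else X_train.mean(axis=0)
            if not (means > 0).all():
                raise ValueError("degenerate all-zero column in a training fold")
            X_train = X_train / means
            X_test = X_test / means
        model = model_factory(X_train, yv[train_idx])
        y_pred = np.asarray(model.predict(X_test), dtype=int)
        rows.append(
            {"fold": fold_id, **compute_metrics(confusion(yv[test_idx], y_pred))}
        )
        pooled_true.append(yv[test_idx])
        pooled_pred.append(y_pred)
    per_fold = pd.DataFrame(rows)
    pooled = compute_metrics(
        confusion(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    )
    macro = per_fold[["accuracy", "precision", "recall", "f_measure"]].mean()
    return MetricsReport(
        model_name=model_name,
        accuracy=float(macro["accuracy"]),
        precision=float(macro["precision"]),
        recall=float(macro["recall"]),
        f_measure=float(macro["f_measure"]),
        per_fold=per_fold,
        pooled=pooled,
        aggregation="macro",
    )


def default_ssa_config(seed: int = 0, pop_size: int = 20, max_iter: int = 50) -> SSAConfig:
    """SSA settings searching (log10 C, log10 sigma) over the default box."""
    return SSAConfig(
        bounds=DEFAULT_LOG10_BOUNDS,
        pop_size=pop_size,
        max_iter=max_iter,
        seed=seed,
    )


def fit_ssa_lssvm(
    X: FeatureMatrix | np.ndarray,
    y: BinaryLabels | np.ndarray,
    ssa: SSAConfig | None = None,
    inner_cv: CVConfig | None = None,
    normalize: bool = True,
) -> tuple[LSSVMModel, OptimizationResult]:
    """Tune (C, sigma) with the sparrow search and refit on all the data.

    The swarm minimizes the mean inner-CV misclassification rate at the
    candidate pair, searching in log10 space. The returned model is
    trained on all rows (mean-normalized when ``normalize``) at the best
    pair, and carries the normalization means so held-out data can be
    scaled identically.
    """
    Xv = _as_array(X)
    yv = _as_labels(y)
    if np.unique(yv).size < 2:
        raise ValueError("labels contain a single class")
    ssa = ssa or default_ssa_config()
    inner_cv = inner_cv or CVConfig(k=5, repetitions=1, seed=ssa.seed)
    folds = make_folds(yv, inner_cv)  # fixed once: fitness is deterministic

    def fitness(position: np.ndarray) -> float:
        C = 10.0 ** position[0]
        sigma = 10.0 ** position[1]
        errors = []
        for train_idx, test_idx in folds:
            X_train, X_test = Xv[train_idx], Xv[test_idx]
            if normalize:
                means = X_train.mean(axis=0)
                X_train = X_train / means
                X_test = X_test / means
            try:
                model = train_lssvm(X_train, yv[train_idx], C=C, sigma=sigma)
            except np.linalg.LinAlgError:
                return np.inf
            errors.append(np.mean(model.predict(X_test) != yv[test_idx]))
        return float(np.mean(errors))

    result = ssa_minimize(fitness, ssa)
    C = 10.0 ** result.best_position[0]
    sigma = 10.0 ** result.best_position[1]
    logger.info(
        "SSA selected C=%.4g sigma=%.4g (inner-CV error %.4f, %d evaluations)",
        C, sigma, result.best_fitness, result.evaluations,
    )
    feature_names = X.feature_names if isinstance(X, FeatureMatrix) else None
    if normalize:
        fm = X if isinstance(X, FeatureMatrix) else FeatureMatrix(
            Xv, tuple(f"x{i}" for i in range(Xv.shape[1]))
        )
        normed = normalize_features(fm)
        model = train_lssvm(
            normed.values, yv, C=C, sigma=sigma,
            feature_names=feature_names,
            normalization_means=normed.normalization_means,
        )
    else:
        model = train_lssvm(Xv, yv, C=C, sigma=sigma, feature_names=feature_names)
    return model, result


def _tuned_lssvm_factory(
    X: FeatureMatrix | np.ndarray,
    y: BinaryLabels | np.ndarray,
    ssa: SSAConfig,
    inner_cv: CVConfig | None = None,
) -> tuple[Callable, tuple[float, float]]:
    """Tune once by inner-CV SSA, return a fixed-(C, sigma) factory."""
    model, _ = fit_ssa_lssvm(X, y, ssa=ssa, inner_cv=inner_cv)
    return lssvm_factory(C=model.C, sigma=model.sigma), (model.C, model.sigma)


def compare_baselines(
    X: FeatureMatrix | np.ndarray,
    y: BinaryLabels | np.ndarray,
    cv: CVConfig | None = None,
    models: Sequence[str] = (
        "KNN", "NaiveBayes", "DecisionTree", "LDA", "LSSVM", "SSA-LSSVM"
    ),
    ssa: SSAConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, MetricsReport]]:
    """Evaluate the requested models under identical fold assignments.

    Returns a summary table (one row per model, macro metrics) and the
    full per-model reports. SSA-LSSVM is tuned once by inner-CV sparrow
    search, then evaluated at the fixed pair, so all models see exactly
    the same folds.
    """
    cv = cv or CVConfig()
    yv = _as_labels(y)
    folds = make_folds(yv, cv)
    logger.info("paired folds digest %s", fold_hash(folds)[:16])
    reports: dict[str, MetricsReport] = {}
    for name in models:
        if name in BASELINE_MODELS:
            builder = BASELINE_MODELS[name]
            seed = _derived_seed(cv.seed, 10_000)
            factory = lambda Xt, yt, _b=builder, _s=seed: sklearn_factory(_b)(Xt, yt, _s)
        elif name == "LSSVM":
            factory = lssvm_factory(C=1.0, sigma=1.0)
        elif name == "SSA-LSSVM":
            factory, pair = _tuned_lssvm_factory(
                X, y, ssa or default_ssa_config(seed=cv.seed)
            )
            logger.info("SSA-LSSVM evaluated at C=%.4g sigma=%.4g", *pair)
        else:
            raise ValueError(f"unknown model name {name!r}")
        reports[name] = repeated_kfold(
            X, y, factory, cv=cv, folds=folds, model_name=name
        )
    table = pd.DataFrame(
        [
            {
                "model": r.model_name,
                "accuracy": r.accuracy,
                "precision": r.precision,
                "recall": r.recall,
                "f_measure": r.f_measure,
            }
            for r in reports.values()
        ]
    )
    return table, reports


def feature_subset_experiment(
    records,
    task: str,
    subset: Sequence[str],
    cv: CVConfig | None = None,
    ssa: SSAConfig | None = None,
    threshold: float | None = None,
    feature_set: Sequence[str] | None = None,
) -> dict:
    """Retrain on a feature subset and compare with the full set.

    Both models are tuned (inner-CV SSA, each on its own feature view)
    and evaluated under the *identical* fold assignment. Returns the two
    reports and a difference row (subset minus full).
    """
    from .records import FULL_FEATURE_SET, extract_features, make_labels

    full_set = tuple(feature_set or FULL_FEATURE_SET)
    subset = tuple(subset)
    if not set(subset) < set(full_set):
        raise ValueError("subset must be a proper subset of the full feature set")
    cv = cv or CVConfig()
    labels = make_labels(records, task, threshold)
    X_full = extract_features(records, full_set)
    X_sub = extract_features(records, subset)
    folds = make_folds(labels.values, cv)
    reports = {}
    for key, Xf in (("full", X_full), ("subset", X_sub)):
        factory, _ = _tuned_lssvm_factory(
            Xf, labels, ssa or default_ssa_config(seed=cv.seed)
        )
        reports[key] = repeated_kfold(
            Xf, labels, factory, cv=cv, folds=folds,
            model_name=f"SSA-LSSVM[{key}]",
        )
    difference = {
        m: getattr(reports["subset"], m) - getattr(reports["full"], m)
        for m in ("accuracy", "precision", "recall", "f_measure")
    }
    return {"full": reports["full"], "subset": reports["subset"],
            "difference": difference, "task": task}


def export_parallel_coordinates(
    X: FeatureMatrix,
    y: BinaryLabels,
    path: str | Path,
) -> pd.DataFrame:
    """Write the long-format table behind a parallel-coordinate plot.

    One row per (sample, feature): sample id, feature name, normalized
    value, class label. Requires a normalized feature matrix.
    """
    if X.normalization_means is None:
        raise ValueError("export requires a normalized feature matrix")
    yv = _as_labels(y)
    if yv.size != X.n:
        raise ValueError("label length must match feature rows")
    frame = pd.DataFrame(X.values, columns=list(X.feature_names))
    frame["sample"] = np.arange(X.n)
    frame["label"] = yv
    tidy = frame.melt(
        id_vars=["sample", "label"], var_name="feature", value_name="value"
    )[["sample", "feature", "value", "label"]]
    tidy.to_csv(path, index=False, float_format="%.10g")
    return tidy
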