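"""Classifier training and evaluation under nested cross-validation.

The baseline classifier is L1-penalized logistic regression: minimizing
the negative log-likelihood L plus λ·Σ|β_j|, with C = 1/λ the inverse
regularization strength (scikit-learn convention; smaller C = sparser
model).  Comparators are an L1/L2 linear SVC, a random forest, and a
feature-selection-aided unpenalized logistic regression where the
univariate t-test p-value threshold is itself a tuned hyperparameter.

Performance estimation follows a 5×5 nested cross-validation: an outer
stratified 5-fold (80% train / 20% test) wraps an inner 5-fold exhaustive
grid search that optimizes plain accuracy; the reported metric is balanced
accuracy on the outer test folds.  Each benchmark cell is replicated on
independently simulated datasets (default 3) and summarized as mean ± sd.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVC

from .features import FeatureMatrix, Standardizer, encode_dataset
from .repertoires import SequenceModel, _spawn_seeds
from .signals import (
    ImplantingSpec,
    LabeledRepertoireDataset,
    Signal,
    build_labeled_dataset,
    random_signal,
)

__all__ = [
    "ConfusionCounts",
    "TrainingConfig",
    "CVResult",
    "PerformancePoint",
    "ExperimentCell",
    "balanced_accuracy",
    "confusion_counts",
    "train_model",
    "nested_cv",
    "simulate_cell_dataset",
    "replicate_experiment",
    "evaluate_transfer",
    "FeatureSelectedLogReg",
]

logger = logging.getLogger(__name__)

# scikit-learn ≥1.8 announces an API migration for the penalty argument;
# the fitted models are unaffected
warnings.filterwarnings("ignore", message=".*'penalty' was deprecated.*")
warnings.filterwarnings("ignore", message=".*Inconsistent values: penalty=.*")

MODEL_KINDS = ("logreg_l1", "svc_l1", "svc_l2", "random_forest", "fs_logreg")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """½(TP/(TP+FN) + TN/(TN+FP)); both classes must be present."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("balanced accuracy undefined when a class is empty")
    sensitivity = counts.tp / (counts.tp + counts.fn)
    specificity = counts.tn / (counts.tn + counts.fp)
    return 0.5 * (sensitivity + specificity)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
    )


@dataclass(frozen=True)
class TrainingConfig:
    """Model kind, hyperparameter grids and CV layout."""

    model_kind: str = "logreg_l1"
    C_grid: tuple[float, ...] = (0.05, 0.1, 1.0, 5.0)
    max_iterations: int = 500
    rf_tree_grid: tuple[int, ...] = (5, 10, 50, 100)
    # selection thresholds span the Bonferroni scale of the 10^4–10^6-feature
    # k-mer spaces: a lenient threshold on 160,000 tests would retain hundreds
    # of chance features and swamp the unpenalized model
    p_value_grid: tuple[float, ...] = (1e-7, 1e-6, 1e-5, 1e-4)
    n_outer_folds: int = 5
    n_inner_folds: int = 5
    optimize_balanced_accuracy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if not self.C_grid or any(c <= 0 for c in self.C_grid):
            raise ValueError("C grid must be non-empty with C > 0")
        if not self.rf_tree_grid or not self.p_value_grid:
            raise ValueError("hyperparameter grids must be non-empty")


class FeatureSelectedLogReg(BaseEstimator, ClassifierMixin):
    """Unpenalized logistic regression on t-test-selected features.

    A two-sided pooled-variance (Student's) t-test compares the two class
    distributions per feature on the training data; features with
    p < ``p_threshold`` are retained.  If nothing survives the threshold
    the model falls back to an intercept-only (majority-class) predictor.
    """

    def __init__(self, p_threshold=0.05, max_iter=500, random_state=None):
        self.p_threshold = p_threshold
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("FeatureSelectedLogReg requires exactly two classes")
        if not sp.issparse(X):
            X = np.asarray(X, dtype=float)
        _, pvals = two_sample_ttest(X, y == self.classes_[1])
        self.support_ = pvals < self.p_threshold
        self.n_selected_ = int(self.support_.sum())
        if self.n_selected_ == 0:
            logger.info(
                "p threshold %g retained no features; intercept-only fallback",
                self.p_threshold,
            )
            # intercept-only logistic regression predicts the majority class
            counts = [(y == c).sum() for c in self.classes_]
            self.majority_ = self.classes_[int(np.argmax(counts))]
            self.model_ = None
            return self
        self.model_ = LogisticRegression(
            penalty=None, max_iter=self.max_iter, random_state=self.random_state
        ).fit(self._select(X), y)
        return self

    def _select(self, X):
        cols = np.flatnonzero(self.support_)
        sub = X[:, cols]
        return sub.toarray() if sp.issparse(sub) else np.asarray(sub, dtype=float)

    def predict(self, X):
        if self.model_ is None:
            return np.full(X.shape[0], self.majority_)
        return self.model_.predict(self._select(X))


def two_sample_ttest(X, group_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided pooled-variance t-test per column.

    Columns with zero variance in both groups get t = 0, p = 1 when the
    group means agree and p = 0 when they differ (degenerate separation).
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    n1 = int(group_mask.sum())
    n2 = int((~group_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 rows for a t-test")
    if sp.issparse(X):
        X1, X2 = X[group_mask], X[~group_mask]
        m1 = np.asarray(X1.mean(axis=0)).ravel()
        m2 = np.asarray(X2.mean(axis=0)).ravel()
        ss1 = np.asarray(X1.multiply(X1).sum(axis=0)).ravel() - n1 * m1**2
        ss2 = np.asarray(X2.multiply(X2).sum(axis=0)).ravel() - n2 * m2**2
    else:
        X = np.asarray(X, dtype=float)
        X1, X2 = X[group_mask], X[~group_mask]
        m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
        ss1 = ((X1 - m1) ** 2).sum(axis=0)
        ss2 = ((X2 - m2) ** 2).sum(axis=0)
    dof = n1 + n2 - 2
    pooled_var = np.clip(ss1 + ss2, 0.0, None) / dof
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    degenerate = (se == 0) & (diff != 0)
    p[degenerate] = 0.0
    t[degenerate] = np.inf * np.sign(diff[degenerate])
    p[(se == 0) & (diff == 0)] = 1.0
    return t, p


def _base_estimator(config: TrainingConfig, seed: int):
    """Estimator plus its grid (pipeline parameter names)."""
    kind = config.model_kind
    # liblinear represents the intercept as an extra penalized feature; a
    # large intercept_scaling keeps that penalty negligible, approximating
    # the unpenalized-intercept objective
    if kind == "logreg_l1":
        est = LogisticRegression(
            penalty="l1",
            solver="liblinear",
            max_iter=config.max_iterations,
            intercept_scaling=100.0,
            random_state=seed,
        )
        grid = {"clf__C": sorted(config.C_grid)}
    elif kind == "svc_l1":
        est = LinearSVC(
            penalty="l1",
            loss="squared_hinge",
            dual=False,
            max_iter=config.max_iterations,
            intercept_scaling=100.0,
            random_state=seed,
        )
        grid = {"clf__C": sorted(config.C_grid)}
    elif kind == "svc_l2":
        est = LinearSVC(
            penalty="l2",
            max_iter=config.max_iterations,
            intercept_scaling=100.0,
            random_state=seed,
        )
        grid = {"clf__C": sorted(config.C_grid)}
    elif kind == "random_forest":
        est = RandomForestClassifier(random_state=seed)
        grid = {"clf__n_estimators": sorted(config.rf_tree_grid)}
    elif kind == "fs_logreg":
        est = FeatureSelectedLogReg(
            max_iter=config.max_iterations, random_state=seed
        )
        # ascending thresholds => the tie-break favours fewer retained features
        grid = {"clf__p_threshold": sorted(config.p_value_grid)}
    else:  # pragma: no cover - guarded by TrainingConfig
        raise ValueError(kind)
    return est, grid


def _make_pipeline(config: TrainingConfig, seed: int) -> tuple[Pipeline, dict]:
    # sparse-preserving variance scaling: with a free intercept, centering
    # standardized features only reparametrizes the intercept, so the model
    # pipeline keeps the k-mer matrix sparse
    est, grid = _base_estimator(config, seed)
    return Pipeline([("standardize", Standardizer(with_mean=False)), ("clf", est)]), grid


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")


def train_model(
    X,
    y,
    model_kind: str = "logreg_l1",
    hyperparameters: dict | None = None,
    seed: int = 0,
    config: TrainingConfig | None = None,
) -> Pipeline:
    """Fit one model (standardizer + classifier) with fixed hyperparameters.

    Non-convergence within the iteration cap is logged, not fatal.
    """
    config = config or TrainingConfig(model_kind=model_kind, seed=seed)
    y = np.asarray(y)
    _check_two_classes(y)
    pipeline, _ = _make_pipeline(config, seed)
    if hyperparameters:
        pipeline.set_params(
            **{f"clf__{k.removeprefix('clf__')}": v for k, v in hyperparameters.items()}
        )
    X = X.values if isinstance(X, FeatureMatrix) else X
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        pipeline.fit(X, y)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            logger.info("model did not converge within the iteration cap: %s", w.message)
    return pipeline


@dataclass
class CVResult:
    """Per-outer-fold balanced accuracies and chosen hyperparameters."""

    fold_scores: list[float]
    chosen_hyperparameters: list[dict]
    models: list[Pipeline] | None = None

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean(self.fold_scores))


def nested_cv(
    dataset,
    config: TrainingConfig | None = None,
    y=None,
    return_models: bool = False,
) -> CVResult:
    """5×5 stratified nested CV with exhaustive inner grid search.

    ``dataset`` is a :class:`FeatureMatrix` (with ``y`` given separately)
    or any (X, y) pair.  The inner search optimizes plain accuracy (the
    tuning metric); the reported outer metric is balanced accuracy.  Grid
    ties resolve to the first grid point in ascending order (strongest
    regularization / fewest retained features).
    """
    config = config or TrainingConfig()
    if isinstance(dataset, FeatureMatrix):
        X = dataset.values
    elif isinstance(dataset, tuple):
        X, y = dataset
    else:
        X = dataset
    if y is None:
        raise ValueError("labels are required")
    y = np.asarray(y)
    if len(y) < 10:
        raise ValueError("nested CV needs at least 10 examples")
    _check_two_classes(y)

    seeds = _spawn_seeds(config.seed, config.n_outer_folds + 1)
    outer = StratifiedKFold(
        n_splits=config.n_outer_folds, shuffle=True, random_state=seeds[0]
    )
    scoring = (
        "balanced_accuracy" if config.optimize_balanced_accuracy else "accuracy"
    )
    fold_scores: list[float] = []
    chosen: list[dict] = []
    models: list[Pipeline] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, (train_idx, test_idx) in enumerate(outer.split(np.zeros(len(y)), y)):
            y_train, y_test = y[train_idx], y[test_idx]
            if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
                raise ValueError("a CV fold lacks one of the classes")
            pipeline, grid = _make_pipeline(config, seeds[i + 1])
            search = GridSearchCV(
                pipeline,
                grid,
                scoring=scoring,
                cv=StratifiedKFold(
                    n_splits=config.n_inner_folds,
                    shuffle=True,
                    random_state=seeds[i + 1],
                ),
                n_jobs=None,
            )
            search.fit(X[train_idx], y_train)
            y_pred = search.predict(X[test_idx])
            fold_scores.append(balanced_accuracy(confusion_counts(y_test, y_pred)))
            chosen.append(
                {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
            )
            if return_models:
                models.append(search.best_estimator_)
    return CVResult(
        fold_scores=fold_scores,
        chosen_hyperparameters=chosen,
        models=models if return_models else None,
    )


@dataclass(frozen=True)
class PerformancePoint:
    """Mean ± sd balanced accuracy of one benchmark cell."""

    mean_balanced_accuracy: float
    sd_balanced_accuracy: float
    n_replications: int
    coordinates: tuple[tuple[str, object], ...] = ()
    replicate_scores: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_balanced_accuracy <= 1.0:
            raise ValueError("mean balanced accuracy must lie in [0, 1]")
        if self.sd_balanced_accuracy < 0:
            raise ValueError("sd must be non-negative")
        if self.n_replications < 1:
            raise ValueError("need at least one replication")


@dataclass(frozen=True)
class ExperimentCell:
    """Simulation + training parameters of one benchmark grid cell."""

    witness_rate: float  # percent
    n_examples: int = 200
    repertoire_size: int = 100_000
    n_motifs: int = 3
    motif_size: int = 4
    gapped: bool = False
    noise_rate: float = 0.0
    positive_fraction: float = 0.5
    encoding_k: int | None = None  # defaults to motif_size
    signal: Signal | None = None
    sequence_model: SequenceModel | None = None

    @property
    def k(self) -> int:
        return self.encoding_k if self.encoding_k is not None else self.motif_size

    def coordinates(self) -> tuple[tuple[str, object], ...]:
        return (
            ("witness_rate", self.witness_rate),
            ("n_examples", self.n_examples),
            ("repertoire_size", self.repertoire_size),
            ("n_motifs", self.n_motifs),
            ("motif_size", self.motif_size),
        )


def simulate_cell_dataset(
    cell: ExperimentCell, seed: int = 0, dataset_id: str = "dataset"
) -> LabeledRepertoireDataset:
    """Simulate one labeled dataset for a benchmark cell."""
    signal_seed, data_seed = _spawn_seeds(seed, 2)
    signal = cell.signal or random_signal(
        cell.n_motifs, cell.motif_size, gapped=cell.gapped, seed=signal_seed
    )
    spec = ImplantingSpec(
        witness_rate=cell.witness_rate,
        noise_rate=cell.noise_rate,
        positive_fraction=cell.positive_fraction,
    )
    return build_labeled_dataset(
        n_examples=cell.n_examples,
        repertoire_size=cell.repertoire_size,
        signal=signal,
        spec=spec,
        model=cell.sequence_model,
        seed=data_seed,
        dataset_id=dataset_id,
    )


def evaluate_cell_dataset(
    dataset: LabeledRepertoireDataset,
    k: int,
    config: TrainingConfig,
    return_models: bool = False,
) -> CVResult:
    encoded = encode_dataset(dataset, k)
    return nested_cv(encoded, config, y=dataset.labels, return_models=return_models)


def replicate_experiment(
    cell: ExperimentCell,
    n_replications: int = 3,
    config: TrainingConfig | None = None,
    seed: int = 0,
) -> PerformancePoint:
    """Simulate and evaluate ``n_replications`` independent datasets.

    Each replication draws a fresh signal and fresh repertoires from a
    distinct sub-seed; the mean and (sample) sd of the per-replication
    nested-CV balanced accuracies are returned.
    """
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    config = config or TrainingConfig()
    seeds = _spawn_seeds(seed, n_replications)
    scores = []
    for r in range(n_replications):
        dataset = simulate_cell_dataset(cell, seed=seeds[r], dataset_id=f"rep{r}")
        result = evaluate_cell_dataset(
            dataset, cell.k, replace(config, seed=seeds[r])
        )
        scores.append(result.mean_balanced_accuracy)
    sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    return PerformancePoint(
        mean_balanced_accuracy=float(np.mean(scores)),
        sd_balanced_accuracy=sd,
        n_replications=n_replications,
        coordinates=cell.coordinates(),
        replicate_scores=tuple(scores),
    )


def evaluate_transfer(
    train_dataset: LabeledRepertoireDataset,
    test_dataset: LabeledRepertoireDataset,
    config: TrainingConfig | None = None,
    k: int = 4,
) -> float:
    """Balanced accuracy under a train/test witness-rate shift.

    Hyperparameters are selected by an inner grid search on the full
    training dataset; the final model is refit on all training examples.
    The test dataset is encoded with the training feature index (unseen
    test k-mers are dropped) and standardized with the training
    standardizer (part of the fitted pipeline).
    """
    config = config or TrainingConfig()
    train_encoded = encode_dataset(train_dataset, k)
    pipeline, grid = _make_pipeline(config, config.seed)
    search = GridSearchCV(
        pipeline,
        grid,
        scoring="balanced_accuracy"
        if config.optimize_balanced_accuracy
        else "accuracy",
        cv=StratifiedKFold(
            n_splits=config.n_inner_folds, shuffle=True, random_state=config.seed
        ),
        n_jobs=None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        search.fit(train_encoded.values, train_dataset.labels)
        test_encoded = encode_dataset(
            test_dataset, k, feature_index=train_encoded.feature_index
        )
        y_pred = search.predict(test_encoded.values)
    return balanced_accuracy(confusion_counts(test_dataset.labels, y_pred))
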