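"""Supervised classification and cross-validated ROC evaluation.

Six fixed-hyperparameter classifiers (random forest, linear SVM, AdaBoost,
Gaussian naive Bayes, decision tree, k-nearest neighbors), stratified
five-fold cross-validation, fold-averaged ROC/AUC, and normalized Gini
feature importance.

The public surface follows the Model/Results idiom: build an
:class:`EnhancerModel` from a :class:`~markcast.features.LabeledFeatureMatrix`,
call :meth:`~EnhancerModel.fit`, and read fold AUCs, the averaged ROC
curve and feature importances off the returned :class:`CVReport`, whose
``summary()`` renders a text table. The underlying operations
(:func:`stratified_folds`, :func:`train_score`, :func:`roc_and_auc`,
:func:`cross_validate`, :func:`gini_importance`) are plain functions.

AUC is computed with the Mann-Whitney rank statistic (midrank tie
correction), which equals the trapezoidal area under the stepped ROC
curve. The displayed fold-averaged curve is a vertical (TPR at fixed FPR)
average on a 101-point grid; the reported mean AUC is the arithmetic mean
of per-fold AUCs, never the area of the averaged curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, EvaluationError
from .features import LabeledFeatureMatrix

ALGORITHMS = (
    "random_forest",
    "linear_svm",
    "adaboost",
    "gaussian_nb",
    "decision_tree",
    "knn",
)
TREE_ALGORITHMS = ("random_forest", "decision_tree")

#: Fixed hyperparameters per algorithm. Construction with other values
#: requires ``allow_override=True`` on :class:`ClassifierSpec`.
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "random_forest": {"n_estimators": 10, "max_depth": 5, "criterion": "gini"},
    "linear_svm": {"penalty": "l2", "C": 0.1},
    "adaboost": {"n_estimators": 50, "learning_rate": 1.0, "base_max_depth": 1},
    "gaussian_nb": {},
    "decision_tree": {"max_depth": 5, "criterion": "gini"},
    "knn": {"k": 3},
}

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the six algorithms with its fixed hyperparameters."""

    algorithm: str
    hyperparams: dict = field(default_factory=dict)
    allow_override: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        defaults = DEFAULT_HYPERPARAMS[self.algorithm]
        unknown = set(self.hyperparams) - set(defaults)
        if unknown:
            raise ConfigurationError(
                f"unknown hyperparameters for {self.algorithm}: {sorted(unknown)}"
            )
        changed = {
            k: v for k, v in self.hyperparams.items() if v != defaults[k]
        }
        if changed and not self.allow_override:
            raise ConfigurationError(
                f"non-default hyperparameters {changed} require allow_override=True"
            )
        object.__setattr__(
            self, "hyperparams", {**defaults, **self.hyperparams}
        )

    @property
    def is_tree_based(self) -> bool:
        return self.algorithm in TREE_ALGORITHMS


@dataclass(frozen=True)
class CVConfig:
    """Stratified k-fold setup; five folds unless stated otherwise."""

    n_folds: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")


@dataclass
class ROCCurve:
    """A stepped ROC curve: non-decreasing fpr/tpr from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {
            "fpr": [float(x) for x in self.fpr],
            "tpr": [float(x) for x in self.tpr],
            "auc": float(self.auc),
        }


def _make_estimator(spec: ClassifierSpec, seed: int):
    hp = spec.hyperparams
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"],
            criterion=hp["criterion"],
            random_state=seed,
        )
    if spec.algorithm == "linear_svm":
        return LinearSVC(penalty=hp["penalty"], C=hp["C"], random_state=seed)
    if spec.algorithm == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=hp["base_max_depth"]),
            n_estimators=hp["n_estimators"],
            learning_rate=hp["learning_rate"],
            random_state=seed,
        )
    if spec.algorithm == "gaussian_nb":
        return GaussianNB()
    if spec.algorithm == "decision_tree":
        return DecisionTreeClassifier(
            max_depth=hp["max_depth"], criterion=hp["criterion"], random_state=seed
        )
    raise ConfigurationError(f"no estimator for {spec.algorithm}")  # knn is custom


def _knn_scores(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, k: int
) -> np.ndarray:
    """Fraction of the k nearest training rows labeled 1.

    Euclidean distance on the binary features; distance ties are broken
    by training-row order (stable argsort), which sklearn's neighbor
    search does not guarantee.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    d2 = (
        (X_test**2).sum(axis=1)[:, None]
        - 2.0 * X_test @ X_train.T
        + (X_train**2).sum(axis=1)[None, :]
    )
    order = np.argsort(np.round(d2, 9), axis=1, kind="stable")[:, :k]
    return np.asarray(y_train, dtype=float)[order].mean(axis=1)


def train_score(
    spec: ClassifierSpec,
    train: LabeledFeatureMatrix,
    test_features: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit on ``train`` and return one real score per test row (higher =
    more positive).

    Scores: RF = mean per-tree class-1 probability; linear SVM = signed
    decision value; AdaBoost = staged decision sum (decision_function);
    naive Bayes = posterior log-odds; decision tree = class-1
    probability; KNN = fraction of the 3 nearest neighbors labeled 1.
    """
    train.require_two_classes()
    X, y = train.features.astype(float), train.labels.astype(int)
    Xt = np.asarray(test_features, dtype=float)
    if spec.algorithm == "knn":
        return _knn_scores(X, y, Xt, spec.hyperparams["k"])
    est = _make_estimator(spec, seed)
    est.fit(X, y)
    if spec.algorithm in ("random_forest", "decision_tree"):
        return est.predict_proba(Xt)[:, 1]
    if spec.algorithm in ("linear_svm", "adaboost"):
        return est.decision_function(Xt)
    if spec.algorithm == "gaussian_nb":
        lp = est.predict_log_proba(Xt)
        return lp[:, 1] - lp[:, 0]
    raise ConfigurationError(f"unknown algorithm {spec.algorithm!r}")


def stratified_folds(
    labels: Sequence[int], config: CVConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold split as (train, test) index pairs.

    The test folds partition all indices; per-fold class counts are within
    1 of exact stratification. Raises :class:`EvaluationError` on
    single-class labels or when ``n_folds`` exceeds the minority count.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise EvaluationError("labels must contain both classes")
    if config.n_folds > len(y):
        raise EvaluationError(
            f"n_folds={config.n_folds} exceeds sample count {len(y)}"
        )
    # stratification needs >= n_folds members per class; below that the
    # split degrades to a plain shuffled partition (every index still
    # tested exactly once)
    if config.stratified and counts.min() >= config.n_folds:
        splitter = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
    return [
        (train.copy(), test.copy())
        for train, test in splitter.split(np.zeros_like(y), y)
    ]


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic with midrank tie correction."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes required to compute AUC")
    ranks = rankdata(s)  # midranks
    return float(
        (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """Stepped ROC curve over unique score thresholds plus its AUC.

    The AUC is the Mann-Whitney statistic; it equals the trapezoidal area
    under the curve (ties collapse to single diagonal segments).
    """
    auc = mann_whitney_auc(scores, labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


def average_curves(curves: Sequence[ROCCurve]) -> ROCCurve:
    """Vertical (TPR at fixed FPR) average on the 101-point grid.

    The endpoints are pinned to (0,0) and (1,1); the stored ``auc`` is the
    trapezoidal area of the averaged curve itself, for plotting only.
    """
    grid = FPR_GRID
    tprs = []
    for c in curves:
        t = np.interp(grid, c.fpr, c.tpr)
        t[0] = 0.0
        t[-1] = 1.0
        tprs.append(t)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return ROCCurve(
        fpr=grid.copy(), tpr=mean_tpr, auc=float(np.trapezoid(mean_tpr, grid))
    )


def gini_importance(
    spec: ClassifierSpec, matrix: LabeledFeatureMatrix, seed: int = 0
) -> dict[str, float]:
    """Normalized Gini (mean decrease in impurity) feature importances.

    Fits the tree-based classifier on the full matrix; importances sum to
    1. Only defined for random_forest and decision_tree.
    """
    if not spec.is_tree_based:
        raise ConfigurationError(
            f"Gini importance requires a tree-based algorithm, got {spec.algorithm}"
        )
    matrix.require_two_classes()
    est = _make_estimator(spec, seed)
    est.fit(matrix.features.astype(float), matrix.labels.astype(int))
    imp = np.asarray(est.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:  # degenerate: no split used any feature
        imp = np.full(len(imp), 1.0 / len(imp))
    else:
        imp = imp / total
    return dict(zip(matrix.dataset_ids, imp.tolist()))


@dataclass
class CVReport:
    """Cross-validation results: per-fold ROC curves, fold AUCs, their
    mean, the vertically averaged curve, and (for tree-based classifiers)
    normalized Gini importances from a full-data fit."""

    spec: ClassifierSpec
    per_fold: list[ROCCurve]
    mean_auc: float
    averaged_curve: ROCCurve
    importances: dict[str, float] | None = None

    @property
    def fold_aucs(self) -> list[float]:
        return [c.auc for c in self.per_fold]

    @property
    def std_auc(self) -> float:
        return float(np.std(self.fold_aucs))

    def to_dict(self) -> dict:
        return {
            "algorithm": self.spec.algorithm,
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": float(self.mean_auc),
            "averaged_curve": self.averaged_curve.to_dict(),
            "importances": self.importances,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def summary(self) -> str:
        lines = [
            "Cross-validated enhancer classification",
            "=" * 45,
            f"algorithm:   {self.spec.algorithm}",
            f"folds:       {len(self.per_fold)}",
            "fold AUCs:   " + ", ".join(f"{a:.3f}" for a in self.fold_aucs),
            f"mean AUC:    {self.mean_auc:.3f} (sd {self.std_auc:.3f})",
        ]
        if self.importances:
            lines.append("")
            lines.append("normalized Gini feature importance")
            lines.append("-" * 45)
            ranked = sorted(
                self.importances.items(), key=lambda kv: kv[1], reverse=True
            )
            for did, imp in ranked:
                lines.append(f"  {did:<28s} {imp:.3f}")
        return "\n".join(lines)

    def plot_roc(self, ax=None, label: str | None = None):
        """Plot per-fold curves (faint) and the averaged curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c in self.per_fold:
            ax.plot(c.fpr, c.tpr, color="0.7", lw=0.8, alpha=0.6)
        ax.plot(
            self.averaged_curve.fpr,
            self.averaged_curve.tpr,
            lw=2,
            label=label or f"{self.spec.algorithm} (mean AUC {self.mean_auc:.2f})",
        )
        ax.plot([0, 1], [0, 1], ls="--", color="0.4", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax


def cross_validate(
    spec: ClassifierSpec, matrix: LabeledFeatureMatrix, config: CVConfig,
    compute_importances: bool | None = None,
) -> CVReport:
    """Stratified k-fold evaluation of one classifier on one matrix.

    Per-fold ROC/AUC is computed on held-out rows only; ``mean_auc`` is
    the arithmetic mean of fold AUCs. Importances come from a full-data
    fit (tree-based classifiers only; pass ``compute_importances=False``
    to skip, or ``True`` to demand them).
    """
    matrix.require_two_classes()
    folds = stratified_folds(matrix.labels, config)
    curves = []
    for k, (train_idx, test_idx) in enumerate(folds):
        train = LabeledFeatureMatrix(
            [matrix.region_ids[i] for i in train_idx],
            matrix.features[train_idx],
            matrix.labels[train_idx],
            list(matrix.dataset_ids),
            list(matrix.meta),
        )
        scores = train_score(
            spec, train, matrix.features[test_idx],
            seed=(config.seed * 1000 + k) % (2**31),
        )
        curves.append(roc_and_auc(scores, matrix.labels[test_idx]))
    if compute_importances is None:
        compute_importances = spec.is_tree_based
    importances = (
        gini_importance(spec, matrix, seed=config.seed)
        if compute_importances
        else None
    )
    return CVReport(
        spec=spec,
        per_fold=curves,
        mean_auc=float(np.mean([c.auc for c in curves])),
        averaged_curve=average_curves(curves),
        importances=importances,
    )


class EnhancerModel:
    """Cross-context enhancer classifier over a labeled feature matrix.

    Parameters
    ----------
    matrix : LabeledFeatureMatrix
        Binary overlap features with 0/1 activity labels.
    algorithm : str
        One of :data:`ALGORITHMS` (default ``"random_forest"``).
    spec : ClassifierSpec, optional
        Full spec; overrides ``algorithm`` when given.

    Examples
    --------
    >>> model = EnhancerModel(matrix, algorithm="random_forest")
    >>> res = model.fit(cv=CVConfig(n_folds=5, seed=1))
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(
        self,
        matrix: LabeledFeatureMatrix,
        algorithm: str = "random_forest",
        spec: ClassifierSpec | None = None,
    ):
        matrix.require_two_classes()
        self.matrix = matrix
        self.spec = spec if spec is not None else ClassifierSpec(algorithm)

    @classmethod
    def from_regions(
        cls,
        positives,
        negatives,
        peak_sets,
        meta,
        algorithm: str = "random_forest",
        min_bp: int = 1,
    ) -> "EnhancerModel":
        """Build the model straight from region sets plus a manifest."""
        from .features import build_feature_matrix

        return cls(
            build_feature_matrix(positives, negatives, peak_sets, meta, min_bp),
            algorithm=algorithm,
        )

    def fit(
        self, cv: CVConfig | None = None, compute_importances: bool | None = None
    ) -> CVReport:
        """Run stratified cross-validation; returns a :class:`CVReport`."""
        return cross_validate(
            self.spec,
            self.matrix,
            cv if cv is not None else CVConfig(),
            compute_importances=compute_importances,
        )
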