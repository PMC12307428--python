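"""Multi-classifier benchmark with stratified k-fold cross-validation.

Eight classifier families are catalogued, each with the variants of the
usual desktop-toolbox presets (tree depth caps, SVM kernel scales, MLP
layer widths, ...).  The exact hyperparameters are this repository's
versioned approximations — the source toolbox publishes none — and live in
:data:`CATALOG`.

Cross-validation is stratified, shuffled and seeded; feature
standardization (z-scoring fitted on the training folds only) is applied
for the scale-sensitive families (SVM, kNN, neural nets, kernel
approximation) and switchable.  Accuracy is the trace/total of the
confusion matrix, which for the two-class case reduces exactly to
(TP + TN) / (TP + FN + TN + FP).

Because one number per family is conventionally reported while families
have several variants, :func:`best_per_family` takes the maximum mean
accuracy over a family's variants (a repo convention, flagged as such);
:func:`run_grid` also emits the full per-variant table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.kernel_approximation import RBFSampler
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .selection import EmptyFeatureSetError, FeatureTable, reduce_table, select_features

#: families whose estimators need feature standardization
SCALE_SENSITIVE = frozenset({"svm", "knn", "neural_net", "kernel_approx"})


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density estimates.

    Silverman's rule sets one bandwidth per (class, feature); likelihoods
    are evaluated feature-chunked to bound memory.
    """

    def __init__(self, min_bandwidth: float = 1e-9, chunk: int = 64):
        self.min_bandwidth = min_bandwidth
        self.chunk = chunk

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._train = []
        self._bandwidth = []
        self._log_prior = []
        for c in self.classes_:
            Xc = X[y == c]
            n = Xc.shape[0]
            sd = Xc.std(axis=0, ddof=1) if n > 1 else np.zeros(Xc.shape[1])
            h = 0.9 * np.maximum(sd, self.min_bandwidth) * n ** (-0.2)
            self._train.append(Xc)
            self._bandwidth.append(h)
            self._log_prior.append(np.log(n / X.shape[0]))
        return self

    def _class_log_likelihood(self, X, Xc, h):
        n_test, p = X.shape
        out = np.zeros(n_test)
        for lo in range(0, p, self.chunk):
            hi = min(lo + self.chunk, p)
            # (test, train, feat) kernel distances for this feature chunk
            z = (X[:, None, lo:hi] - Xc[None, :, lo:hi]) / h[lo:hi]
            dens = np.exp(-0.5 * z**2).mean(axis=1) / (np.sqrt(2 * np.pi) * h[lo:hi])
            out += np.log(np.maximum(dens, 1e-300)).sum(axis=1)
        return out

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.column_stack(
            [
                lp + self._class_log_likelihood(X, Xc, h)
                for Xc, h, lp in zip(self._train, self._bandwidth, self._log_prior)
            ]
        )
        return self.classes_[np.argmax(scores, axis=1)]


def _gaussian_svm(scale_factor: float, n_features: int, random_state: int) -> SVC:
    # toolbox convention: kernel scale sigma = factor * sqrt(P), gamma = 1/sigma^2
    sigma = scale_factor * np.sqrt(n_features)
    return SVC(kernel="rbf", gamma=1.0 / sigma**2, C=1.0, random_state=random_state)


#: family -> variant -> factory(n_features, random_state) -> estimator
CATALOG: dict[str, dict[str, callable]] = {
    "decision_tree": {
        "fine": lambda p, rs: DecisionTreeClassifier(max_leaf_nodes=100, random_state=rs),
        "medium": lambda p, rs: DecisionTreeClassifier(max_leaf_nodes=20, random_state=rs),
        "coarse": lambda p, rs: DecisionTreeClassifier(max_leaf_nodes=4, random_state=rs),
    },
    "discriminant": {
        "linear": lambda p, rs: LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
        "quadratic": lambda p, rs: QuadraticDiscriminantAnalysis(reg_param=0.1),
    },
    "naive_bayes": {
        "gaussian": lambda p, rs: GaussianNB(),
        "kernel": lambda p, rs: KernelNaiveBayes(),
    },
    "svm": {
        "linear": lambda p, rs: SVC(kernel="linear", C=1.0, random_state=rs),
        "quadratic": lambda p, rs: SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=1.0, random_state=rs),
        "cubic": lambda p, rs: SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale", C=1.0, random_state=rs),
        "fine_gaussian": lambda p, rs: _gaussian_svm(0.25, p, rs),
        "medium_gaussian": lambda p, rs: _gaussian_svm(1.0, p, rs),
        "coarse_gaussian": lambda p, rs: _gaussian_svm(4.0, p, rs),
    },
    "knn": {
        "cubic": lambda p, rs: KNeighborsClassifier(n_neighbors=10, p=3),
        "cosine": lambda p, rs: KNeighborsClassifier(n_neighbors=10, metric="cosine"),
    },
    "ensemble": {
        "boosted_trees": lambda p, rs: AdaBoostClassifier(
            DecisionTreeClassifier(max_leaf_nodes=20), n_estimators=30, random_state=rs
        ),
        "bagged_trees": lambda p, rs: RandomForestClassifier(n_estimators=30, random_state=rs),
        "subspace_discriminant": lambda p, rs: BaggingClassifier(
            LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
            n_estimators=30, max_features=0.5, random_state=rs,
        ),
        "subspace_knn": lambda p, rs: BaggingClassifier(
            KNeighborsClassifier(n_neighbors=10),
            n_estimators=30, max_features=0.5, random_state=rs,
        ),
        "rusboosted_trees": lambda p, rs: AdaBoostClassifier(
            DecisionTreeClassifier(max_leaf_nodes=20, class_weight="balanced"),
            n_estimators=30, random_state=rs,
        ),
    },
    "neural_net": {
        "narrow": lambda p, rs: MLPClassifier((10,), max_iter=400, random_state=rs),
        "medium": lambda p, rs: MLPClassifier((25,), max_iter=400, random_state=rs),
        "wide": lambda p, rs: MLPClassifier((100,), max_iter=400, random_state=rs),
        "bilayered": lambda p, rs: MLPClassifier((10, 10), max_iter=400, random_state=rs),
        "trilayered": lambda p, rs: MLPClassifier((10, 10, 10), max_iter=400, random_state=rs),
    },
    "kernel_approx": {
        "svm": lambda p, rs: make_pipeline(
            RBFSampler(n_components=256, random_state=rs),
            SGDClassifier(loss="hinge", random_state=rs),
        ),
        "logistic": lambda p, rs: make_pipeline(
            RBFSampler(n_components=256, random_state=rs),
            LogisticRegression(max_iter=500, random_state=rs),
        ),
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    variant: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in CATALOG:
            raise ValueError(f"unknown family {self.family!r}; expected one of {list(CATALOG)}")
        if self.variant not in CATALOG[self.family]:
            raise ValueError(
                f"variant {self.variant!r} not in {self.family}'s catalog "
                f"{list(CATALOG[self.family])}"
            )

    @property
    def name(self) -> str:
        return f"{self.family}/{self.variant}"


def all_specs(families: list[str] | None = None) -> list[ClassifierSpec]:
    """Every catalogued (family, variant) pair, optionally family-filtered."""
    families = families or list(CATALOG)
    return [ClassifierSpec(f, v) for f in families for v in CATALOG[f]]


def build_estimator(
    spec: ClassifierSpec, n_features: int, random_state: int = 0, standardize: bool = True
):
    est = CATALOG[spec.family][spec.variant](n_features, random_state)
    if spec.hyperparameters:
        est.set_params(**spec.hyperparameters)
    if standardize and spec.family in SCALE_SENSITIVE:
        est = make_pipeline(StandardScaler(), est)
    return est


def accuracy(confusion: np.ndarray) -> float:
    """trace/total of a square, nonnegative-integer confusion matrix."""
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1] or confusion.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    if np.any(confusion < 0) or not np.issubdtype(confusion.dtype, np.integer):
        raise ValueError("confusion matrix must hold nonnegative integers")
    total = confusion.sum()
    if total == 0:
        raise ValueError("confusion matrix has zero total")
    return float(np.trace(confusion) / total)


@dataclass
class CVResult:
    fold_accuracies: list[float]
    confusion: np.ndarray
    spec: ClassifierSpec
    feature_set: str
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def pooled_accuracy(self) -> float:
        return accuracy(self.confusion)


def crossval(
    table: FeatureTable,
    spec: ClassifierSpec,
    k: int = 5,
    seed: int = 0,
    standardize: bool = True,
    feature_set: str = "",
) -> CVResult:
    """Stratified, seeded k-fold CV of one classifier on one feature table."""
    y = table.labels
    X = table.values
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= k={k} samples (min is {counts.min()})")

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    pooled = np.zeros((classes.size, classes.size), dtype=int)
    est0 = build_estimator(spec, X.shape[1], random_state=seed, standardize=standardize)
    for train_idx, test_idx in splitter.split(X, y):
        est = clone(est0)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        cm = confusion_matrix(y[test_idx], pred, labels=classes)
        pooled += cm
        fold_acc.append(accuracy(cm))
    return CVResult(
        fold_accuracies=fold_acc,
        confusion=pooled,
        spec=spec,
        feature_set=feature_set,
        seed=seed,
    )


def run_grid(
    tables: dict[str, FeatureTable],
    specs: list[ClassifierSpec],
    k: int = 5,
    seed: int = 0,
    alpha: float | None = 0.05,
    scope: str = "subject_independent",
    standardize: bool = True,
) -> pd.DataFrame:
    """CV every spec on every table, full and (optionally) ANOVA-reduced.

    Returns a long-format results table with one row per fold plus a
    ``fold="mean"`` row per run.  An ANOVA reduction that leaves no
    columns is recorded as a not-available row rather than aborting.
    """
    rows: list[dict] = []

    def emit(name: str, reduced: bool, result: CVResult | None) -> None:
        base = {
            "subject_scope": scope,
            "feature_set": name,
            "reduced": reduced,
            "seed": seed,
        }
        if result is None:
            rows.append({**base, "family": None, "variant": None, "fold": "mean",
                         "accuracy": np.nan, "mean_accuracy": np.nan})
            return
        for i, acc in enumerate(result.fold_accuracies):
            rows.append({**base, "family": result.spec.family, "variant": result.spec.variant,
                         "fold": str(i + 1), "accuracy": acc,
                         "mean_accuracy": result.mean_accuracy})
        rows.append({**base, "family": result.spec.family, "variant": result.spec.variant,
                     "fold": "mean", "accuracy": result.mean_accuracy,
                     "mean_accuracy": result.mean_accuracy})

    for name, table in tables.items():
        variants: list[tuple[bool, FeatureTable | None]] = [(False, table)]
        if alpha is not None:
            mask = select_features(table, alpha=alpha)
            try:
                variants.append((True, reduce_table(table, mask)))
            except EmptyFeatureSetError:
                variants.append((True, None))
        for reduced, tab in variants:
            if tab is None:
                emit(name, reduced, None)
                continue
            for spec in specs:
                result = crossval(
                    tab, spec, k=k, seed=seed, standardize=standardize,
                    feature_set=name,
                )
                emit(name, reduced, result)
    return pd.DataFrame(rows)


def best_per_family(results: pd.DataFrame) -> pd.DataFrame:
    """Max mean accuracy over each family's variants (repo convention)."""
    means = results[results["fold"] == "mean"].dropna(subset=["mean_accuracy"])
    keys = ["subject_scope", "feature_set", "reduced", "family"]
    idx = means.groupby(keys)["mean_accuracy"].idxmax()
    return (
        means.loc[idx, keys + ["variant", "mean_accuracy"]]
        .sort_values(keys)
        .reset_index(drop=True)
    )
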