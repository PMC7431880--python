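"""The 19-classifier benchmark: cross-validation, confusion-matrix
metrics, and paired comparison of the three representation approaches.

The classifier panel reproduces a fixed catalogue of configurations:
three decision trees (maximum 100/20/4 splits), linear and quadratic
discriminant analysis, SVMs with linear/quadratic/cubic/Gaussian
kernels, five KNN variants (fine k=1 Euclidean, medium k=10 Euclidean,
cosine k=10, cubic-distance k=10, and k=10 weighted by inverse squared
Euclidean distance), four ensembles (bagged trees, boosted trees,
random-subspace discriminant, random-subspace KNN), and a feed-forward
neural network with one hidden layer of 10 units.

All approaches share one stratified 5-fold partition so per-classifier
metrics are paired, which the Wilcoxon signed-rank comparison requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .selection import select_top_k, ttest_rank
from .timelapse import fit_apply_normalization

__all__ = [
    "CLASSIFIER_NAMES",
    "APPROACHES",
    "POSITIVE_CLASS",
    "BenchmarkReport",
    "build_classifier",
    "make_splits",
    "cross_validate",
    "confusion_metrics",
    "compare_approaches",
    "run_benchmark",
    "plot_benchmark",
]

APPROACHES = ("static", "value_based", "feature_based")

#: Mesenchymal is the positive class throughout.
POSITIVE_CLASS = "mesenchymal"

CLASSIFIER_NAMES = (
    "tree-complex",
    "tree-medium",
    "tree-simple",
    "lda",
    "qda",
    "svm-linear",
    "svm-quadratic",
    "svm-cubic",
    "svm-gaussian",
    "knn-fine",
    "knn-medium",
    "knn-cosine",
    "knn-cubic",
    "knn-weighted",
    "ensemble-bagged-trees",
    "ensemble-boosted-trees",
    "ensemble-subspace-discriminant",
    "ensemble-subspace-knn",
    "neural-net",
)

_ENSEMBLE_SIZE = 30


def _inverse_square(distances: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(distances, 1e-12) ** 2


def build_classifier(name: str, seed: int = 0, n_features: int = 10):
    """Construct one named classifier configuration (deterministic under
    ``seed``).  ``n_features`` sets data-dependent defaults: the Gaussian
    SVM kernel scale sqrt(n_features) and the subspace dimension
    ceil(sqrt(n_features))."""
    subspace = max(1, int(np.ceil(np.sqrt(n_features))))
    gamma = 1.0 / n_features  # kernel scale sqrt(n_features)
    builders = {
        "tree-complex": lambda: DecisionTreeClassifier(max_leaf_nodes=101, random_state=seed),
        "tree-medium": lambda: DecisionTreeClassifier(max_leaf_nodes=21, random_state=seed),
        "tree-simple": lambda: DecisionTreeClassifier(max_leaf_nodes=5, random_state=seed),
        "lda": lambda: LinearDiscriminantAnalysis(),
        # small covariance ridge: selected features can be collinear or
        # constant within a class (e.g. saturated SAX symbols)
        "qda": lambda: QuadraticDiscriminantAnalysis(reg_param=1e-3),
        "svm-linear": lambda: SVC(kernel="linear", random_state=seed),
        "svm-quadratic": lambda: SVC(kernel="poly", degree=2, coef0=1.0, random_state=seed),
        "svm-cubic": lambda: SVC(kernel="poly", degree=3, coef0=1.0, random_state=seed),
        "svm-gaussian": lambda: SVC(kernel="rbf", gamma=gamma, random_state=seed),
        "knn-fine": lambda: KNeighborsClassifier(n_neighbors=1),
        "knn-medium": lambda: KNeighborsClassifier(n_neighbors=10),
        "knn-cosine": lambda: KNeighborsClassifier(n_neighbors=10, metric="cosine"),
        "knn-cubic": lambda: KNeighborsClassifier(n_neighbors=10, metric="minkowski", p=3),
        "knn-weighted": lambda: KNeighborsClassifier(
            n_neighbors=10, weights=_inverse_square
        ),
        "ensemble-bagged-trees": lambda: BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=_ENSEMBLE_SIZE,
            random_state=seed,
        ),
        "ensemble-boosted-trees": lambda: AdaBoostClassifier(
            n_estimators=_ENSEMBLE_SIZE, random_state=seed
        ),
        "ensemble-subspace-discriminant": lambda: BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=_ENSEMBLE_SIZE,
            bootstrap=False,
            max_features=min(subspace, n_features),
            random_state=seed,
        ),
        "ensemble-subspace-knn": lambda: BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=_ENSEMBLE_SIZE,
            bootstrap=False,
            max_features=min(subspace, n_features),
            random_state=seed,
        ),
        "neural-net": lambda: MLPClassifier(
            hidden_layer_sizes=(10,),
            activation="logistic",
            solver="lbfgs",
            max_iter=500,
            random_state=seed,
        ),
    }
    if name not in builders:
        raise ValueError(f"unknown classifier variant {name!r}")
    return builders[name]()


def confusion_metrics(
    cm: np.ndarray, positive_index: int = 1
) -> Tuple[float, float, float, float]:
    """Accuracy, precision, recall and F-score of a 2x2 count matrix.

    ``cm[i, j]`` counts samples of true class i predicted as class j;
    undefined ratios (empty denominators) report 0 by convention.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (2, 2) or cm.min() < 0 or cm.sum() == 0:
        raise ValueError("need a non-empty 2x2 non-negative count matrix")
    p = positive_index
    tp = cm[p, p]
    fn = cm[p, 1 - p]
    fp = cm[1 - p, p]
    accuracy = np.trace(cm) / cm.sum()
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f_score = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return float(accuracy), float(precision), float(recall), float(f_score)


@dataclass
class BenchmarkReport:
    """Per-(approach, classifier) metrics with fold detail and paired
    approach comparisons."""

    metrics: pd.DataFrame  # index (approach, classifier), 4 metric columns
    fold_metrics: pd.DataFrame  # adds a fold level
    confusions: Dict[Tuple[str, str], np.ndarray]
    comparisons: Optional[pd.DataFrame] = None
    seed: Optional[int] = None

    def metric_vector(self, approach: str, metric: str = "accuracy") -> np.ndarray:
        sub = self.metrics.loc[approach]
        return sub.loc[list(CLASSIFIER_NAMES), metric].to_numpy()

    def summary(self) -> pd.DataFrame:
        rows = []
        for approach in self.metrics.index.get_level_values(0).unique():
            sub = self.metrics.loc[approach]
            rows.append(
                {"approach": approach}
                | {f"{m}_mean": sub[m].mean() for m in sub.columns}
                | {f"{m}_sd": sub[m].std(ddof=1) for m in sub.columns}
            )
        return pd.DataFrame(rows)


def plot_benchmark(report: "BenchmarkReport", path) -> None:
    """Box-whisker plots of the per-classifier metric distributions for
    each approach (one panel per metric)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    approaches = list(report.metrics.index.get_level_values(0).unique())
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, metric in zip(axes.ravel(), ("accuracy", "precision", "recall", "f_score")):
        data = [report.metrics.loc[a][metric].to_numpy() for a in approaches]
        ax.boxplot(data, tick_labels=approaches)
        ax.set_title(metric)
        ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def make_splits(
    labels: np.ndarray, folds: int = 5, seed: int = 0
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """One stratified partition shared by every classifier and approach."""
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(labels.size), labels))


def _positive_index(classes: np.ndarray) -> int:
    classes = list(classes)
    return classes.index(POSITIVE_CLASS) if POSITIVE_CLASS in classes else 1


def cross_validate(
    matrix: np.ndarray,
    labels: np.ndarray,
    classifier_names: Sequence[str] = CLASSIFIER_NAMES,
    folds: int = 5,
    seed: int = 0,
    splits: Optional[List[Tuple[np.ndarray, np.ndarray]]] = None,
    approach: str = "feature_based",
) -> BenchmarkReport:
    """Stratified k-fold evaluation of the classifier panel on one matrix."""
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    splits = splits if splits is not None else make_splits(labels, folds, seed)
    classes = np.unique(labels)
    pos = _positive_index(classes)
    records = []
    confusions: Dict[Tuple[str, str], np.ndarray] = {}
    for name in classifier_names:
        pooled = np.zeros((2, 2))
        for fold, (train_idx, test_idx) in enumerate(splits):
            model = build_classifier(name, seed=seed, n_features=matrix.shape[1])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(matrix[train_idx], labels[train_idx])
                pred = model.predict(matrix[test_idx])
            cm = np.zeros((2, 2))
            for ti, pi in zip(labels[test_idx], pred):
                cm[np.searchsorted(classes, ti), np.searchsorted(classes, pi)] += 1
            pooled += cm
            acc, prec, rec, f1 = confusion_metrics(cm, pos)
            records.append(
                {
                    "approach": approach,
                    "classifier": name,
                    "fold": fold,
                    "accuracy": acc,
                    "precision": prec,
                    "recall": rec,
                    "f_score": f1,
                }
            )
        confusions[(approach, name)] = pooled
    fold_metrics = pd.DataFrame(records).set_index(["approach", "classifier", "fold"])
    metrics = fold_metrics.groupby(level=["approach", "classifier"], sort=False).mean()
    return BenchmarkReport(
        metrics=metrics, fold_metrics=fold_metrics, confusions=confusions, seed=seed
    )


def compare_approaches(
    metric_vectors: Dict[str, np.ndarray]
) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank tests between approach pairs.

    Zero differences are dropped (classic Wilcoxon convention); a pair
    with no nonzero differences reports statistic NaN and p = 1 with a
    note.
    """
    names = list(metric_vectors)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(metric_vectors[names[i]], dtype=float)
            b = np.asarray(metric_vectors[names[j]], dtype=float)
            if a.shape != b.shape:
                raise ValueError("paired metric vectors must share length")
            diffs = a - b
            if np.all(diffs == 0):
                rows.append(
                    {
                        "approach_a": names[i],
                        "approach_b": names[j],
                        "statistic": float("nan"),
                        "p_value": 1.0,
                        "note": "all differences zero; no test performed",
                    }
                )
                continue
            stat, p = sstats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
            rows.append(
                {
                    "approach_a": names[i],
                    "approach_b": names[j],
                    "statistic": float(stat),
                    "p_value": float(p),
                    "note": "",
                }
            )
    return pd.DataFrame(rows)


def run_benchmark(
    matrices: Dict[str, np.ndarray],
    labels: np.ndarray,
    top_k: Optional[Dict[str, int]] = None,
    folds: int = 5,
    seed: int = 0,
    mode: str = "nested",
    classifier_names: Sequence[str] = CLASSIFIER_NAMES,
    metric_for_comparison: str = "accuracy",
    series_flat: Optional[np.ndarray] = None,
    n_pca: int = 3,
) -> BenchmarkReport:
    """Evaluate every approach on a shared CV partition and compare them.

    ``matrices`` maps approach name -> (cells x features) matrix over the
    same cells in the same order.  In nested mode, normalisation, t-test
    selection and (when ``series_flat`` is given) the PCA block of the
    feature-based vector are refitted on each training fold; in paper
    mode they are fitted once on the full data before the CV loop.
    ``series_flat`` holds the flattened n x d series per cell and feeds
    the PCA score columns appended to the feature-based matrix.
    ``top_k`` gives the retained feature count per approach (defaults:
    10 for static and feature-based, 12 for value-based).
    """
    from .selection import DEFAULT_K_FEATURE_BASED, DEFAULT_K_VALUE_BASED
    from .timelapse import PCAFeatures

    if mode not in ("nested", "paper"):
        raise ValueError("mode must be 'nested' or 'paper'")
    labels = np.asarray(labels)
    n = labels.size
    for name, m in matrices.items():
        if np.asarray(m).shape[0] != n:
            raise ValueError(f"matrix {name!r} does not cover all cells")
    top_k = top_k or {}
    defaults = {
        "static": DEFAULT_K_FEATURE_BASED,
        "feature_based": DEFAULT_K_FEATURE_BASED,
        "value_based": DEFAULT_K_VALUE_BASED,
    }
    splits = make_splits(labels, folds, seed)
    classes = np.unique(labels)
    pos = _positive_index(classes)
    all_fold_records = []
    confusions: Dict[Tuple[str, str], np.ndarray] = {}
    for approach, matrix in matrices.items():
        matrix = np.asarray(matrix, dtype=float)
        with_pca = approach == "feature_based" and series_flat is not None
        k = top_k.get(approach, defaults.get(approach, 10))
        if mode == "paper":
            if with_pca:
                pca = PCAFeatures(n_pca).fit(series_flat)
                matrix = np.hstack([matrix, pca.transform(series_flat)])
            k = min(k, matrix.shape[1])
            scaled, _, _ = fit_apply_normalization(matrix)
            ranking = ttest_rank(scaled, labels).ranking
            reduced = select_top_k(scaled, ranking, k)
            fold_data = [
                (reduced[tr], reduced[te], tr, te) for tr, te in splits
            ]
        else:
            fold_data = []
            for tr, te in splits:
                m_train, m_test = matrix[tr], matrix[te]
                if with_pca:
                    pca = PCAFeatures(n_pca).fit(series_flat[tr])
                    m_train = np.hstack([m_train, pca.transform(series_flat[tr])])
                    m_test = np.hstack([m_test, pca.transform(series_flat[te])])
                kk = min(k, m_train.shape[1])
                train_s, test_s, _ = fit_apply_normalization(m_train, m_test)
                ranking = ttest_rank(train_s, labels[tr]).ranking
                fold_data.append(
                    (
                        select_top_k(train_s, ranking, kk),
                        select_top_k(test_s, ranking, kk),
                        tr,
                        te,
                    )
                )
        for name in classifier_names:
            pooled = np.zeros((2, 2))
            for fold, (X_train, X_test, tr, te) in enumerate(fold_data):
                model = build_classifier(name, seed=seed, n_features=X_train.shape[1])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X_train, labels[tr])
                    pred = model.predict(X_test)
                cm = np.zeros((2, 2))
                for ti, pi in zip(labels[te], pred):
                    cm[np.searchsorted(classes, ti), np.searchsorted(classes, pi)] += 1
                pooled += cm
                acc, prec, rec, f1 = confusion_metrics(cm, pos)
                all_fold_records.append(
                    {
                        "approach": approach,
                        "classifier": name,
                        "fold": fold,
                        "accuracy": acc,
                        "precision": prec,
                        "recall": rec,
                        "f_score": f1,
                    }
                )
            confusions[(approach, name)] = pooled
    fold_metrics = pd.DataFrame(all_fold_records).set_index(
        ["approach", "classifier", "fold"]
    )
    metrics = fold_metrics.groupby(level=["approach", "classifier"], sort=False).mean()
    vectors = {
        approach: metrics.loc[approach]
        .loc[list(classifier_names), metric_for_comparison]
        .to_numpy()
        for approach in matrices
    }
    comparisons = compare_approaches(vectors)
    return BenchmarkReport(
        metrics=metrics,
        fold_metrics=fold_metrics,
        confusions=confusions,
        comparisons=comparisons,
        seed=seed,
    )
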