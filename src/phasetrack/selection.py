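"""Filter feature selection: t-test ranking, p-value ECDF, and error-vs-k
tuning of the retained feature count.

Features are ranked by the p-value of a Welch two-sample t-test between
the two classes.  The empirical CDF of the p-values summarises how much
of the feature set carries class signal.  The number of retained
features is chosen by scanning a grid of k, estimating for each k the
cross-validated classification error averaged over a panel of fast
classifiers, and taking the argmin (ties towards the smallest k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionReport",
    "ttest_rank",
    "pvalue_cdf",
    "choose_k",
    "select_top_k",
    "DEFAULT_K_FEATURE_BASED",
    "DEFAULT_K_VALUE_BASED",
]

#: Default retained-feature counts for the two time-lapse approaches.
DEFAULT_K_FEATURE_BASED = 10
DEFAULT_K_VALUE_BASED = 12


@dataclass
class SelectionReport:
    """Ranking plus optional error-curve diagnostics."""

    feature_names: List[str]
    ranking: np.ndarray  # column indices, best first
    p_values: np.ndarray  # aligned with ranking
    chosen_k: Optional[int] = None
    error_curve: Optional[pd.DataFrame] = None


def ttest_rank(
    matrix: np.ndarray, labels: np.ndarray, feature_names: Optional[Sequence[str]] = None
) -> SelectionReport:
    """Rank features by Welch two-sided two-sample t-test p-values.

    Features constant within both classes get p = 1 when the class means
    agree (no evidence) and p = 0 when they differ (perfect separation).
    Ties in p break towards the lower feature index.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    a = matrix[labels == classes[0]]
    b = matrix[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = sstats.ttest_ind(a, b, equal_var=False)
        p = np.asarray(result.pvalue, dtype=float)
    both_const = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    means_equal = a.mean(axis=0) == b.mean(axis=0)
    p[both_const & means_equal] = 1.0
    p[both_const & ~means_equal] = 0.0
    p[np.isnan(p)] = 1.0
    ranking = np.argsort(p, kind="stable")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(matrix.shape[1])]
    return SelectionReport(
        feature_names=[feature_names[i] for i in ranking],
        ranking=ranking,
        p_values=p[ranking],
    )


def pvalue_cdf(
    p_values: np.ndarray, at: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Empirical CDF of the p-values, evaluated at the sorted p-values and
    at any extra query points (p = 0.05 is always included)."""
    p = np.sort(np.asarray(p_values, dtype=float))
    query = np.unique(np.concatenate([p, [0.05], np.asarray(at, dtype=float) if at is not None else []]))
    cdf = np.searchsorted(p, query, side="right") / p.size
    return pd.DataFrame({"p": query, "ecdf": cdf})


def select_top_k(matrix: np.ndarray, ranking: np.ndarray, k: int) -> np.ndarray:
    """Column subset of the k best-ranked features, in ranked order."""
    ranking = np.asarray(ranking)
    if k > ranking.size:
        raise ValueError("k exceeds the number of ranked features")
    return np.asarray(matrix, dtype=float)[:, ranking[:k]]


def _default_panel(seed: int) -> Dict[str, object]:
    # five fast representatives: tree, LDA, linear SVM, KNN, small ensemble
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import BaggingClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "tree": DecisionTreeClassifier(max_leaf_nodes=21, random_state=seed),
        "lda": LinearDiscriminantAnalysis(),
        "svm_linear": SVC(kernel="linear", random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=1),
        "bagged_trees": BaggingClassifier(
            n_estimators=10, random_state=seed
        ),
    }


def choose_k(
    matrix: np.ndarray,
    labels: np.ndarray,
    k_grid: Sequence[int] = tuple(range(2, 26)),
    classifiers: Optional[Dict[str, object]] = None,
    folds: int = 5,
    seed: int = 0,
    nested: bool = True,
) -> SelectionReport:
    """Choose the retained feature count by minimising mean CV error.

    For each k in the grid, the top-k t-test-ranked features feed every
    panel classifier under a shared stratified k-fold split; the error
    (misclassified fraction) is averaged over folds and classifiers and
    the smallest-error k wins (ties towards smaller k).  In nested mode
    (default) the ranking is recomputed on each training fold so test
    labels never touch selection; otherwise the ranking is global.
    """
    from sklearn.base import clone

    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    k_grid = sorted(set(int(k) for k in k_grid))
    if max(k_grid) > matrix.shape[1]:
        raise ValueError("k grid exceeds the available feature count")
    classifiers = classifiers or _default_panel(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(matrix, labels))
    global_rank = ttest_rank(matrix, labels)
    errors = {name: np.zeros(len(k_grid)) for name in classifiers}
    for train_idx, test_idx in splits:
        rank = (
            ttest_rank(matrix[train_idx], labels[train_idx]).ranking
            if nested
            else global_rank.ranking
        )
        for ki, k in enumerate(k_grid):
            X_train = matrix[np.ix_(train_idx, rank[:k])]
            X_test = matrix[np.ix_(test_idx, rank[:k])]
            for name, model in classifiers.items():
                fitted = clone(model).fit(X_train, labels[train_idx])
                err = np.mean(fitted.predict(X_test) != labels[test_idx])
                errors[name][ki] += err / len(splits)
    curve = pd.DataFrame({"k": k_grid})
    for name in classifiers:
        curve[name] = errors[name]
    curve["mean_error"] = curve[list(classifiers)].mean(axis=1)
    chosen_k = int(curve.loc[curve["mean_error"].idxmin(), "k"])
    return SelectionReport(
        feature_names=global_rank.feature_names,
        ranking=global_rank.ranking,
        p_values=global_rank.p_values,
        chosen_k=chosen_k,
        error_curve=curve,
    )
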