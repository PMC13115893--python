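"""Consensus machine-learning feature selection over screened CpG pools.

Two independent rankers — recursive feature elimination driven by a
linear max-margin classifier (SVM-RFE) and random-forest impurity
importance — rank each pool; a stratified 5-fold cross-validation sweep
picks the optimal top-k subset per ranker (accuracy first, AUC as the
tie-break, then the smaller k); the probes selected by *both* rankers
form the consensus set (T-sites / G-sites), and the union of the two
consensus sets is the integrated feature set (U-sites).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

DEFAULT_ELIM_FRACTION = 0.1
DEFAULT_N_TREES = 500


@dataclass
class FeatureRanking:
    method: str  # "svm_rfe" | "rf"
    ranked_cpg_ids: list[str]  # descending importance; index 0 = rank 1
    scores: np.ndarray  # aligned with ranked_cpg_ids, method-specific units

    def __post_init__(self):
        if len(set(self.ranked_cpg_ids)) != len(self.ranked_cpg_ids):
            raise ValueError("ranking contains duplicates")

    def top(self, k: int) -> list[str]:
        return self.ranked_cpg_ids[:k]


@dataclass
class FeatureSet:
    set_tag: str  # "T-sites" | "G-sites" | "U-sites"
    cpg_ids: set[str]
    source_sizes: tuple[int, int, int] | None = None  # (|A|, |B|, |A∩B|)


def _check_inputs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return X, y


def svm_rfe_ranking(X, y, feature_ids, elim_fraction: float = DEFAULT_ELIM_FRACTION,
                    seed: int = 0, C: float = 1.0) -> FeatureRanking:
    """Recursive feature elimination with a linear max-margin classifier.

    Features are z-scored once; each round fits the classifier on the
    survivors and removes the ``elim_fraction`` of them with the smallest
    squared weights (at least one per round).  The elimination round is
    the score: later-eliminated features rank higher, and the final
    survivors are ordered by |weight|.
    """
    X, y = _check_inputs(X, y)
    feature_ids = list(feature_ids)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / np.where(sd > 0, sd, 1.0)

    surviving = np.arange(X.shape[1])
    elim_order: list[tuple[int, float]] = []  # (feature index, round score)
    round_no = 0
    while surviving.size > 1:
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(Xs[:, surviving], y)
        w2 = np.ravel(clf.coef_) ** 2
        n_drop = max(1, math.floor(elim_fraction * surviving.size))
        # smallest squared weight first; feature index breaks ties
        order = np.lexsort((surviving, w2))
        drop = order[:n_drop]
        for local in drop:
            elim_order.append((surviving[local], round_no))
        keep = np.ones(surviving.size, dtype=bool)
        keep[drop] = False
        surviving = surviving[keep]
        round_no += 1
    elim_order.append((surviving[0], round_no))

    # rank 1 = last surviving
    ranked_idx = [idx for idx, _ in reversed(elim_order)]
    scores = np.array([score for _, score in reversed(elim_order)], dtype=float)
    return FeatureRanking("svm_rfe", [feature_ids[i] for i in ranked_idx],
                          scores)


def rf_importance_ranking(X, y, feature_ids, n_trees: int = DEFAULT_N_TREES,
                          seed: int = 0) -> FeatureRanking:
    """Random-forest mean-decrease-in-impurity ranking, probe-id tie-break."""
    X, y = _check_inputs(X, y)
    feature_ids = list(feature_ids)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(X, y)
    imp = forest.feature_importances_
    order = sorted(range(len(feature_ids)),
                   key=lambda i: (-imp[i], feature_ids[i]))
    return FeatureRanking("rf", [feature_ids[i] for i in order], imp[order])


def _model_for(method: str, seed: int, n_trees: int = 200):
    if method == "svm_rfe":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="linear", C=1.0, random_state=seed)),
        ])
    return RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                  n_jobs=1)


def cv_subset_selection(ranking: FeatureRanking, X, y, feature_ids,
                        size_grid, n_folds: int = 5, seed: int = 0,
                        n_trees: int = 200) -> tuple[int, pd.DataFrame]:
    """Choose the top-k nested subset by stratified k-fold CV.

    Each grid size is evaluated with the ranking's own model family; the
    winner maximizes mean accuracy, with mean AUC then the smaller size
    breaking ties.
    """
    X, y = _check_inputs(X, y)
    size_grid = sorted(set(int(s) for s in size_grid))
    if max(size_grid) > len(ranking.ranked_cpg_ids):
        raise ValueError("size grid exceeds the ranking length")
    col = {f: i for i, f in enumerate(feature_ids)}
    # canonical sample order (label, then feature values) makes the
    # seeded stratified folds invariant to input row order
    canon = np.lexsort(tuple(X.T[::-1]) + (y,))
    X, y = X[canon], y[canon]
    folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    if min(np.bincount(y)) < n_folds:
        raise ValueError(
            "a class has fewer samples than folds; use larger folds"
        )
    rows = []
    for k in size_grid:
        cols = [col[f] for f in ranking.top(k)]
        Xk = X[:, cols]
        accs, aucs = [], []
        for train, test in folds.split(Xk, y):
            model = _model_for(ranking.method, seed, n_trees)
            model.fit(Xk[train], y[train])
            pred = model.predict(Xk[test])
            if hasattr(model, "predict_proba"):
                score = model.predict_proba(Xk[test])[:, 1]
            else:
                score = model.decision_function(Xk[test])
            accs.append(accuracy_score(y[test], pred))
            aucs.append(roc_auc_score(y[test], score))
        rows.append({"size": k, "mean_acc": float(np.mean(accs)),
                     "mean_auc": float(np.mean(aucs))})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["mean_acc", "mean_auc", "size"], ascending=[False, False, True],
        kind="mergesort").iloc[0]
    return int(best["size"]), table


def consensus_sites(a, b, set_tag: str = "T-sites") -> FeatureSet:
    """Probes selected by both rankers (exact intersection)."""
    a, b = set(a), set(b)
    inter = a & b
    if not inter:
        warnings.warn(f"{set_tag}: rankers selected disjoint probe sets")
    return FeatureSet(set_tag, inter, (len(a), len(b), len(inter)))


def union_sites(a: FeatureSet, b: FeatureSet,
                set_tag: str = "U-sites") -> FeatureSet:
    """Union of two consensus sets; the cardinality identity
    |A∪B| = |A| + |B| − |A∩B| is checked."""
    union = a.cpg_ids | b.cpg_ids
    inter = a.cpg_ids & b.cpg_ids
    assert len(union) == len(a.cpg_ids) + len(b.cpg_ids) - len(inter)
    return FeatureSet(set_tag, union,
                      (len(a.cpg_ids), len(b.cpg_ids), len(inter)))
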