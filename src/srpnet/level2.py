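"""Second-level wrapper selection: exhaustive subset search over the candidates.

Every one of the 2^n - 1 non-empty subsets of the candidate feature set
is scored with a bank of seven classical classifiers (SVM, KNN, decision
tree, gradient-boosted trees, random forest, AdaBoost, Gaussian naive
Bayes) by stratified k-fold cross-validated micro precision, and the
subset with the best unweighted mean score across classifiers wins.
Ties break toward smaller subsets, then lexicographic order, so adding
an uninformative column never displaces an equally good smaller set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from joblib import Parallel, delayed
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import FeatureTable, LabelVector
from .level1 import SelectionReport

CLASSIFIER_IDS = ("svm", "knn", "dt", "gbdt", "rf", "adaboost", "gaussian_nb")

#: frozen hyperparameter profiles for the classifier bank.  "default" uses
#: library defaults; "fast" shrinks ensemble sizes for exhaustive sweeps.
CLASSIFIER_PROFILES: dict[str, dict[str, dict]] = {
    "default": {
        "svm": {},
        "knn": {},
        "dt": {},
        "gbdt": {},
        "rf": {},
        "adaboost": {},
        "gaussian_nb": {},
    },
    "fast": {
        "svm": {},
        "knn": {},
        "dt": {"max_depth": 6},
        "gbdt": {"n_estimators": 10, "max_depth": 2},
        "rf": {"n_estimators": 10},
        "adaboost": {"n_estimators": 10},
        "gaussian_nb": {},
    },
}


def make_classifier(classifier_id: str, seed: int, profile: str = "default"):
    """Instantiate one of the seven bank members with a pinned seed."""
    if classifier_id not in CLASSIFIER_IDS:
        raise ValueError(f"unknown classifier {classifier_id!r}; expected one of {CLASSIFIER_IDS}")
    kw = CLASSIFIER_PROFILES[profile][classifier_id]
    if classifier_id == "svm":
        return SVC(random_state=seed, **kw)
    if classifier_id == "knn":
        return KNeighborsClassifier(**kw)
    if classifier_id == "dt":
        return DecisionTreeClassifier(random_state=seed, **kw)
    if classifier_id == "gbdt":
        return GradientBoostingClassifier(random_state=seed, **kw)
    if classifier_id == "rf":
        return RandomForestClassifier(random_state=seed, **kw)
    if classifier_id == "adaboost":
        return AdaBoostClassifier(random_state=seed, **kw)
    return GaussianNB(**kw)


@dataclass
class SubsetScore:
    """Cross-validated micro precision of one feature subset, per classifier."""

    subset: tuple[str, ...]
    per_classifier: dict[str, float]
    mean_score: float

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset),
            "per_classifier": self.per_classifier,
            "mean_score": self.mean_score,
        }


@dataclass
class SubsetSearchResult:
    """Best subset per size and overall, over an exhaustive (or greedy) sweep."""

    best_by_size: dict[int, SubsetScore]
    overall_best: SubsetScore
    n_evaluated: int
    exhaustive: bool = True

    def score_curve(self) -> list[tuple[int, float]]:
        """(subset size, best mean micro precision) pairs, ascending in size."""
        return [(k, self.best_by_size[k].mean_score) for k in sorted(self.best_by_size)]

    def to_dict(self) -> dict:
        return {
            "best_by_size": {k: v.to_dict() for k, v in self.best_by_size.items()},
            "overall_best": self.overall_best.to_dict(),
            "n_evaluated": self.n_evaluated,
            "exhaustive": self.exhaustive,
        }


def enumerate_subsets(
    candidates: Sequence[str], n_max: int = 20
) -> Iterator[tuple[str, ...]]:
    """Yield every non-empty subset exactly once, ordered by (size, lexicographic).

    Lexicographic order is over candidate positions, so the stream is
    deterministic for a fixed candidate ordering.  Guarded by ``n_max``
    because the count is 2^n - 1.
    """
    n = len(candidates)
    if n < 1:
        raise ValueError("candidate set is empty")
    if n > n_max:
        raise ValueError(
            f"{n} candidates would require {2**n - 1} subsets; "
            f"raise n_max or use greedy_forward_search"
        )
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            yield tuple(candidates[i] for i in combo)


def micro_precision_cv(
    X: np.ndarray,
    y: np.ndarray,
    classifier_id: str,
    *,
    cv: int = 5,
    seed: int = 0,
    profile: str = "default",
) -> float:
    """Mean micro precision (accuracy) of a classifier over stratified k-fold CV."""
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cv:
        rare = np.unique(y)[counts.argmin()]
        raise ValueError(
            f"category {rare} has only {counts.min()} subjects; "
            f"cannot stratify into {cv} folds"
        )
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(X, y):
        clf = make_classifier(classifier_id, seed, profile)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        scores.append(float(np.mean(pred == y[test_idx])))
    return float(np.mean(scores))


def evaluate_subset(
    subset: Sequence[str],
    table: FeatureTable,
    labels: LabelVector,
    classifier_id: str,
    *,
    cv: int = 5,
    seed: int = 0,
    profile: str = "default",
) -> float:
    """Cross-validated micro precision of one classifier on one feature subset."""
    sub = table.select(subset)
    return micro_precision_cv(
        sub.values, labels.codes, classifier_id, cv=cv, seed=seed, profile=profile
    )


def _stratified_subsample(
    y: np.ndarray, cap: int, seed: int
) -> np.ndarray:
    """Row indices of a stratified subsample of size <= cap (at least 1 per class)."""
    rng = np.random.default_rng(seed)
    n = y.size
    if n <= cap:
        return np.arange(n)
    keep: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        take = max(1, int(round(cap * idx.size / n)))
        keep.append(rng.choice(idx, size=min(take, idx.size), replace=False))
    return np.sort(np.concatenate(keep))


def _score_subset(
    subset: tuple[str, ...],
    X: np.ndarray,
    y: np.ndarray,
    col_index: dict[str, int],
    cv: int,
    seed: int,
    profile: str,
) -> SubsetScore:
    cols = [col_index[name] for name in subset]
    Xs = X[:, cols]
    per = {
        cid: micro_precision_cv(Xs, y, cid, cv=cv, seed=seed, profile=profile)
        for cid in CLASSIFIER_IDS
    }
    return SubsetScore(
        subset=subset, per_classifier=per, mean_score=float(np.mean(list(per.values())))
    )


def _better(a: SubsetScore, b: SubsetScore | None, order: dict[str, int]) -> bool:
    """True if a beats b: higher mean, then smaller subset, then lexicographic."""
    if b is None:
        return True
    if a.mean_score != b.mean_score:
        return a.mean_score > b.mean_score
    if len(a.subset) != len(b.subset):
        return len(a.subset) < len(b.subset)
    return tuple(order[n] for n in a.subset) < tuple(order[n] for n in b.subset)


def search_optimal(
    report: SelectionReport | Sequence[str],
    table: FeatureTable,
    labels: LabelVector,
    seed: int = 0,
    *,
    cv: int = 5,
    n_max: int = 20,
    profile: str = "default",
    subsample: int | None = 20_000,
    n_jobs: int = 1,
) -> SubsetSearchResult:
    """Exhaustively score all candidate subsets and return the optimum.

    ``report`` may be a level-1 ``SelectionReport`` or a plain candidate
    list.  Rows are capped at ``subsample`` by stratified sampling (seeded)
    so the sweep stays tractable on large cohorts.  Results are independent
    of ``n_jobs``: each subset's CV seed is fixed before dispatch.
    """
    candidates = list(report.candidate_set) if isinstance(report, SelectionReport) else list(report)
    if not candidates:
        raise ValueError("candidate set is empty")
    order = {n: i for i, n in enumerate(table.feature_names)}
    candidates.sort(key=order.__getitem__)

    y = labels.codes
    X = table.values
    if subsample is not None and y.size > subsample:
        rows = _stratified_subsample(y, subsample, seed)
        X, y = X[rows], y[rows]
    col_index = {n: order[n] for n in candidates}

    subsets = list(enumerate_subsets(candidates, n_max=n_max))
    scored: list[SubsetScore] = Parallel(n_jobs=n_jobs)(
        delayed(_score_subset)(s, X, y, col_index, cv, seed, profile) for s in subsets
    )

    cand_order = {n: i for i, n in enumerate(candidates)}
    best_by_size: dict[int, SubsetScore] = {}
    overall: SubsetScore | None = None
    for sc in scored:
        k = len(sc.subset)
        if _better(sc, best_by_size.get(k), cand_order):
            best_by_size[k] = sc
        if _better(sc, overall, cand_order):
            overall = sc
    assert overall is not None
    return SubsetSearchResult(
        best_by_size=best_by_size,
        overall_best=overall,
        n_evaluated=len(subsets),
        exhaustive=True,
    )


def greedy_forward_search(
    candidates: Sequence[str],
    table: FeatureTable,
    labels: LabelVector,
    seed: int = 0,
    *,
    cv: int = 5,
    profile: str = "default",
    subsample: int | None = 20_000,
) -> SubsetSearchResult:
    """Greedy-forward fallback for candidate sets too large to enumerate.

    Grows the subset one best-scoring feature at a time; returns the best
    prefix found.  Evaluates O(n^2) subsets instead of 2^n - 1.
    """
    candidates = list(candidates)
    order = {n: i for i, n in enumerate(table.feature_names)}
    candidates.sort(key=order.__getitem__)
    y = labels.codes
    X = table.values
    if subsample is not None and y.size > subsample:
        rows = _stratified_subsample(y, subsample, seed)
        X, y = X[rows], y[rows]
    col_index = {n: order[n] for n in candidates}
    cand_order = {n: i for i, n in enumerate(candidates)}

    chosen: list[str] = []
    best_by_size: dict[int, SubsetScore] = {}
    overall: SubsetScore | None = None
    n_eval = 0
    remaining = list(candidates)
    while remaining:
        step_best: SubsetScore | None = None
        step_feat: str | None = None
        for feat in remaining:
            subset = tuple(sorted(chosen + [feat], key=cand_order.__getitem__))
            sc = _score_subset(subset, X, y, col_index, cv, seed, profile)
            n_eval += 1
            if _better(sc, step_best, cand_order):
                step_best, step_feat = sc, feat
        assert step_best is not None and step_feat is not None
        chosen.append(step_feat)
        remaining.remove(step_feat)
        best_by_size[len(chosen)] = step_best
        if _better(step_best, overall, cand_order):
            overall = step_best
    assert overall is not None
    return SubsetSearchResult(
        best_by_size=best_by_size,
        overall_best=overall,
        n_evaluated=n_eval,
        exhaustive=False,
    )
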